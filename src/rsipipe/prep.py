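"""Image preparation: resampling to the T2W grid, ADC and high-b derivation,
cropping/normalization into classifier input tensors, and label-safe
augmentation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from nibabel.processing import resample_from_to

from .errors import ConfigurationError

__all__ = [
    "ImagingStudy",
    "ModelInputTensor",
    "AugmentPolicy",
    "BPMRI_CHANNELS",
    "BPMRI_RSI_CHANNELS",
    "resample_to_t2w",
    "compute_adc",
    "select_high_b",
    "assemble_input",
    "augment",
]

BPMRI_CHANNELS: tuple[str, ...] = ("t2w", "adc", "high_b")
BPMRI_RSI_CHANNELS: tuple[str, ...] = ("t2w", "adc", "high_b", "rsi_c1", "rsi_c2")

_SIGNAL_EPS = 1e-6
_ZSCORE_SIGMA_FLOOR = 1e-6


@dataclass
class ImagingStudy:
    """One patient's volumes: T2W, DWI stack keyed by b-value, prostate mask.

    After :func:`resample_to_t2w` all volumes share the T2W grid and affine.
    """

    patient_id: str
    t2w: np.ndarray
    t2w_affine: np.ndarray
    dwi: dict[float, np.ndarray]
    dwi_affine: np.ndarray
    prostate_mask: np.ndarray
    mask_affine: np.ndarray
    adc: np.ndarray | None = None
    high_b: np.ndarray | None = None
    truth: object | None = None

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(sorted(self.dwi))


@dataclass
class ModelInputTensor:
    """Normalized (channel, x, y, z) classifier input plus optional scalar."""

    channels: tuple[str, ...]
    array: np.ndarray
    rsirs_max: float | None = None

    def __post_init__(self) -> None:
        if self.array.ndim != 4 or self.array.shape[0] != len(self.channels):
            raise ConfigurationError("tensor must be (channel, x, y, z) matching channel list")
        if not np.all(np.isfinite(self.array)):
            raise ConfigurationError("tensor contains non-finite values")


def _grids_match(a_shape, a_aff, b_shape, b_aff) -> bool:
    return tuple(a_shape) == tuple(b_shape) and np.allclose(a_aff, b_aff)


def _world_bbox(shape, affine) -> tuple[np.ndarray, np.ndarray]:
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    world = nib.affines.apply_affine(affine, corners)
    return world.min(axis=0), world.max(axis=0)


def _check_overlap(shape_a, aff_a, shape_b, aff_b) -> None:
    lo_a, hi_a = _world_bbox(shape_a, aff_a)
    lo_b, hi_b = _world_bbox(shape_b, aff_b)
    if np.any(hi_a < lo_b) or np.any(hi_b < lo_a):
        raise ConfigurationError("fields of view do not overlap; cannot resample")


def _resample(arr: np.ndarray, affine: np.ndarray, target_shape, target_affine, order: int) -> np.ndarray:
    if _grids_match(arr.shape, affine, target_shape, target_affine):
        return np.asarray(arr, dtype=np.float32)
    _check_overlap(arr.shape, affine, target_shape, target_affine)
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
    out = resample_from_to(img, (tuple(target_shape), target_affine), order=order)
    return np.asarray(out.dataobj, dtype=np.float32)


def resample_to_t2w(study: ImagingStudy) -> ImagingStudy:
    """Trilinearly resample every non-T2W volume onto the T2W grid.

    The prostate mask is resampled nearest-neighbor and re-binarized.
    """
    shape, aff = study.t2w.shape, study.t2w_affine
    dwi = {b: _resample(v, study.dwi_affine, shape, aff, order=1) for b, v in study.dwi.items()}
    mask = _resample(study.prostate_mask.astype(np.float32), study.mask_affine, shape, aff, order=0)
    out = replace(
        study,
        dwi=dwi,
        dwi_affine=aff.copy(),
        prostate_mask=(mask > 0.5).astype(np.uint8),
        mask_affine=aff.copy(),
    )
    if out.adc is not None:
        out.adc = _resample(out.adc, study.dwi_affine, shape, aff, order=1)
    if out.high_b is not None:
        out.high_b = _resample(out.high_b, study.dwi_affine, shape, aff, order=1)
    return out


def compute_adc(
    dwi_stack: dict[float, np.ndarray],
    b_subset: tuple[float, ...] | None = None,
    max_b: float = 1000.0,
) -> np.ndarray:
    """Mono-exponential apparent diffusion coefficient map, mm^2/s.

    Per-voxel least-squares slope of -log(S) versus b over ``b_subset``
    (default: all acquired b-values <= ``max_b``, the conventional clinical
    ADC range). Nonpositive signals are clamped to a small epsilon before the
    logarithm so zero-signal voxels stay finite.
    """
    if b_subset is None:
        b_subset = tuple(b for b in sorted(dwi_stack) if b <= max_b)
    if len(b_subset) < 2:
        raise ConfigurationError("ADC fit needs at least 2 b-values")
    missing = [b for b in b_subset if b not in dwi_stack]
    if missing:
        raise ConfigurationError(f"b-values not in DWI stack: {missing}")
    b = np.asarray(b_subset, dtype=float)
    logs = np.stack(
        [np.log(np.clip(dwi_stack[bv], _SIGNAL_EPS, None)) for bv in b_subset], axis=0
    )
    # slope of log(S) vs b, vectorized: cov(b, logS) / var(b); ADC = -slope
    b_c = b - b.mean()
    denom = float((b_c**2).sum())
    slope = np.tensordot(b_c, logs - logs.mean(axis=0), axes=(0, 0)) / denom
    return (-slope).astype(np.float32)


def select_high_b(dwi_stack: dict[float, np.ndarray]) -> np.ndarray:
    """The acquired volume with the largest b-value (the 'high-b DWI' channel)."""
    if not dwi_stack:
        raise ConfigurationError("empty DWI stack")
    return dwi_stack[max(dwi_stack)]


def _mask_bbox(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nz = np.argwhere(mask > 0)
    if nz.size == 0:
        raise ConfigurationError("empty prostate mask")
    return nz.min(axis=0), nz.max(axis=0)


def _crop_pad_centered(arr: np.ndarray, center: np.ndarray, crop_shape) -> np.ndarray:
    out = np.zeros(tuple(crop_shape), dtype=np.float32)
    start = np.round(center - (np.asarray(crop_shape) - 1) / 2.0).astype(int)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.asarray(crop_shape), arr.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        return out
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = arr[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    return out


def assemble_input(
    study: ImagingStudy,
    rsi_maps: dict[str, np.ndarray] | None,
    channel_set: tuple[str, ...],
    crop_shape: tuple[int, int, int] = (32, 32, 24),
    rsirs_max: float | None = None,
) -> ModelInputTensor:
    """Stack, crop and z-score the requested channels.

    Crop/pad is centered on the prostate-mask bounding-box center; z-score
    statistics are computed over the bounding-box voxels of each channel
    (constant channels normalize to zero via a sigma floor). Channel order is
    the order of ``channel_set``.
    """
    available: dict[str, np.ndarray | None] = {
        "t2w": study.t2w,
        "adc": study.adc,
        "high_b": study.high_b,
    }
    if rsi_maps:
        available.update(rsi_maps)
    lo, hi = _mask_bbox(study.prostate_mask)
    center = (lo + hi) / 2.0
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    planes = []
    for name in channel_set:
        vol = available.get(name)
        if vol is None:
            raise ConfigurationError(f"requested channel '{name}' is missing from the study")
        box = vol[sl].astype(np.float64)
        mu, sd = float(box.mean()), float(box.std())
        sd = max(sd, _ZSCORE_SIGMA_FLOOR)
        planes.append(_crop_pad_centered((vol - mu) / sd, center, crop_shape))
    return ModelInputTensor(
        channels=tuple(channel_set),
        array=np.stack(planes, axis=0).astype(np.float32),
        rsirs_max=rsirs_max,
    )


@dataclass(frozen=True)
class AugmentPolicy:
    """Label-preserving augmentation: left-right flips, small integer
    translations, mild multiplicative intensity jitter."""

    flip_lr: bool = True
    max_translation: int = 2
    intensity_jitter: float = 0.05

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(flip_lr=False, max_translation=0, intensity_jitter=0.0)


def augment(tensor: ModelInputTensor, rng: np.random.Generator, policy: AugmentPolicy) -> ModelInputTensor:
    """Apply one random draw of the policy; deterministic given the rng state.

    Never touches the label or the ``rsirs_max`` scalar.
    """
    arr = tensor.array
    if policy.flip_lr and rng.random() < 0.5:
        arr = arr[:, ::-1, :, :]
    if policy.max_translation > 0:
        shifts = rng.integers(-policy.max_translation, policy.max_translation + 1, size=3)
        arr = np.roll(arr, tuple(shifts), axis=(1, 2, 3))
    if policy.intensity_jitter > 0:
        scale = 1.0 + rng.uniform(-policy.intensity_jitter, policy.intensity_jitter)
        arr = arr * scale
    return ModelInputTensor(channels=tensor.channels, array=np.ascontiguousarray(arr), rsirs_max=tensor.rsirs_max)
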