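"""Synthetic multi-center prostate MRI cohort generator.

Emulates the statistical structure of a seven-center clinically-significant
prostate cancer (csPCa) imaging cohort: site-specific csPCa prevalence and
biopsy-cohort mix, ordinal PI-RADS scores stochastically linked to the csPCa
label, and per-patient volumes (T2-weighted, multi-b-value DWI, prostate mask)
produced by a four-compartment exponential-decay diffusion forward model with
Rician noise.

The default site profiles reproduce the published per-center patient counts,
csPCa counts and biopsy-naïve/biopsy-confirmed (BN-BC) counts of the source
cohort; per-site PI-RADS-given-label conditionals are not public, so a single
documented default pair is used for every site (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CohortIOError, ConfigurationError
from .prep import ImagingStudy

__all__ = [
    "SiteProfile",
    "CohortConfig",
    "GroundTruth",
    "default_site_profiles",
    "default_cohort_config",
    "generate_cohort",
    "synthesize_patient_volumes",
    "write_cohort",
    "read_cohort",
]

# Externally sourced defaults taken from prior restriction spectrum imaging
# work: restricted intracellular, hindered extracellular, free water, and
# vascular/pseudo-diffusion compartments, mm^2/s. Overridable.
DEFAULT_COMPARTMENT_ADCS: tuple[float, float, float, float] = (1.0e-4, 1.8e-3, 3.6e-3, 1.0e-2)
DEFAULT_B_VALUES: tuple[float, ...] = (0.0, 200.0, 1000.0, 2000.0, 3000.0)

# PI-RADS distribution conditional on csPCa status. Chosen once so that the
# implied marginal PI-RADS distribution at 39% prevalence approximates the
# published overall distribution and the implied PI-RADS discrimination is
# realistic (AUC ~ 0.84 between the two conditionals).
DEFAULT_PIRADS_GIVEN_POS: tuple[float, ...] = (0.02, 0.03, 0.10, 0.40, 0.45)
DEFAULT_PIRADS_GIVEN_NEG: tuple[float, ...] = (0.50, 0.05, 0.18, 0.17, 0.10)

COHORT_FLAG_BNBC = "BN-BC"
COHORT_FLAG_PBINC = "PBI-NC"

MANIFEST_COLUMNS = ["patient_id", "site_id", "cohort_flag", "pirads", "cspca_label"]

# Reference in-prostate proton-density signal scale; noise_sigma is expressed
# as a fraction of this value.
S0_REFERENCE = 100.0


@dataclass(frozen=True)
class SiteProfile:
    """Statistical profile of one imaging center."""

    site_id: str
    n_patients: int
    prevalence: float
    bnbc_fraction: float
    pirads_given_pos: tuple[float, ...] = DEFAULT_PIRADS_GIVEN_POS
    pirads_given_neg: tuple[float, ...] = DEFAULT_PIRADS_GIVEN_NEG
    noise_sigma: float = 0.02

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError(f"site {self.site_id}: n_patients must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(f"site {self.site_id}: prevalence outside [0, 1]")
        if not 0.0 <= self.bnbc_fraction <= 1.0:
            raise ConfigurationError(f"site {self.site_id}: bnbc_fraction outside [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"site {self.site_id}: noise_sigma must be nonnegative")
        for name, vec in (
            ("pirads_given_pos", self.pirads_given_pos),
            ("pirads_given_neg", self.pirads_given_neg),
        ):
            v = np.asarray(vec, dtype=float)
            if v.shape != (5,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"site {self.site_id}: {name} must be 5 nonnegative values summing to 1"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic multi-center cohort."""

    sites: tuple[SiteProfile, ...]
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    compartment_adcs: tuple[float, float, float, float] = DEFAULT_COMPARTMENT_ADCS
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    lesion_c1_contrast: float = 2.5
    background_fractions: tuple[float, float, float, float] = (0.15, 0.45, 0.30, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if not self.sites:
            raise ConfigurationError("cohort needs at least one site")
        for site in self.sites:
            site.validate()
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 3 or np.any(np.diff(b) <= 0) or b[0] != 0.0 or np.any(b < 0):
            raise ConfigurationError("b_values must be >=3 ascending nonnegative values starting at 0")
        d = np.asarray(self.compartment_adcs, dtype=float)
        if d.shape != (4,) or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ConfigurationError("compartment_adcs must be 4 positive strictly increasing values")
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ConfigurationError("voxel_spacing must be positive")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ConfigurationError("lesion_radius_range must satisfy 0 < min <= max")
        if self.lesion_c1_contrast <= 0:
            raise ConfigurationError("lesion_c1_contrast must be positive")
        f = np.asarray(self.background_fractions, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ConfigurationError("background_fractions must be 4 nonnegative values summing to 1")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag((*self.voxel_spacing, 1.0))
        return aff


@dataclass
class GroundTruth:
    """Per-patient generative ground truth (labels plus, once volumes are
    synthesized, the true compartment-fraction maps and lesion centers)."""

    patient_id: str
    site_id: str
    cspca_label: int
    cohort_flag: str
    pirads: int
    true_compartment_maps: np.ndarray | None = None  # (4, *grid) fractions
    lesion_centers: list[np.ndarray] = field(default_factory=list)  # mm (world)


def default_site_profiles() -> tuple[SiteProfile, ...]:
    """Seven site profiles with the published per-center counts.

    n_patients, csPCa counts and BN-BC counts match the source cohort's
    per-center characteristics table; prevalence and bnbc_fraction are the
    corresponding exact count ratios so that count arithmetic (e.g. the 876
    BN-BC evaluation subset, 721 csPCa cases) is reproducible from the
    profiles themselves.
    """
    raw = [
        # site_id, n, csPCa count, BN-BC count
        ("UCSD-Health", 692, 252, 309),
        ("UCSD-CTIPM", 647, 269, 259),
        ("MGH", 63, 27, 38),
        ("URMC", 251, 107, 233),
        ("UCSF", 42, 25, 20),
        ("UTHSCSA", 146, 40, 17),
        ("Cambridge", 5, 1, 0),
    ]
    return tuple(
        SiteProfile(
            site_id=sid,
            n_patients=n,
            prevalence=k / n,
            bnbc_fraction=b / n,
        )
        for sid, n, k, b in raw
    )


def site_count_table(profiles: Sequence[SiteProfile] | None = None) -> pd.DataFrame:
    """Expected per-site counts implied by the profiles (cases, csPCa, BN-BC)."""
    profiles = default_site_profiles() if profiles is None else profiles
    rows = []
    for p in profiles:
        rows.append(
            {
                "site_id": p.site_id,
                "n_patients": p.n_patients,
                "n_cspca": round(p.prevalence * p.n_patients),
                "n_bnbc": round(p.bnbc_fraction * p.n_patients),
            }
        )
    return pd.DataFrame(rows)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(sites=default_site_profiles(), seed=seed)


# ---------------------------------------------------------------------------
# Cohort-level sampling
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> tuple[list[GroundTruth], pd.DataFrame]:
    """Draw per-patient labels, cohort flags and PI-RADS scores for every site.

    All randomness flows from ``config.seed``; the same config yields a
    byte-identical manifest. Volumes are synthesized separately by
    :func:`synthesize_patient_volumes`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths: list[GroundTruth] = []
    rows = []
    for site in config.sites:
        labels = rng.binomial(1, site.prevalence, size=site.n_patients)
        flags = rng.binomial(1, site.bnbc_fraction, size=site.n_patients)
        pos = np.asarray(site.pirads_given_pos)
        neg = np.asarray(site.pirads_given_neg)
        for i in range(site.n_patients):
            p = pos if labels[i] == 1 else neg
            pirads = int(rng.choice(5, p=p)) + 1
            pid = f"{site.site_id}-{i:04d}"
            flag = COHORT_FLAG_BNBC if flags[i] == 1 else COHORT_FLAG_PBINC
            truths.append(
                GroundTruth(
                    patient_id=pid,
                    site_id=site.site_id,
                    cspca_label=int(labels[i]),
                    cohort_flag=flag,
                    pirads=pirads,
                )
            )
            rows.append((pid, site.site_id, flag, pirads, int(labels[i])))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return truths, manifest


# ---------------------------------------------------------------------------
# Per-patient imaging forward model
# ---------------------------------------------------------------------------

def _ellipsoid_mask(grid_shape, voxel_spacing) -> np.ndarray:
    """Centered ellipsoidal prostate mask with semi-axes 0.35 of the field of view."""
    shape = np.asarray(grid_shape)
    spacing = np.asarray(voxel_spacing, dtype=float)
    center_mm = (shape - 1) * spacing / 2.0
    semi = 0.35 * shape * spacing
    idx = np.indices(grid_shape).astype(float)
    coords = idx * spacing[:, None, None, None]
    r2 = sum(((coords[a] - center_mm[a]) / semi[a]) ** 2 for a in range(3))
    return (r2 <= 1.0).astype(np.uint8)


def _smooth_field(rng: np.random.Generator, grid_shape, amplitude: float) -> np.ndarray:
    """Zero-mean smooth random field with max |value| <= amplitude."""
    noise = rng.standard_normal(grid_shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    peak = np.max(np.abs(smooth))
    if peak == 0:
        return np.zeros(grid_shape)
    return amplitude * smooth / peak


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI Rician corruption: sqrt((S+n1)^2 + n2^2), n ~ N(0, sigma)."""
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def synthesize_patient_volumes(
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    background_variation: float = 0.02,
    max_lesion_attempts: int = 50,
) -> ImagingStudy:
    """Render one patient's T2W, multi-b DWI stack and prostate mask.

    The DWI signal at voxel v and b-value b is
    ``S0(v) * sum_i C_i(v) * exp(-b * D_i)`` before Rician corruption, with the
    compartment fractions C_i nonnegative and summing to one at every voxel.
    csPCa-positive patients receive one spherical focal lesion inside the mask
    where the restricted fraction C1 is multiplied by ``lesion_c1_contrast``
    and the fractions renormalized. Fills ``truth.true_compartment_maps`` and
    ``truth.lesion_centers`` in place.
    """
    config.validate()
    site = next((s for s in config.sites if s.site_id == truth.site_id), None)
    if site is None:
        raise ConfigurationError(f"patient {truth.patient_id}: unknown site {truth.site_id}")

    grid = tuple(config.grid_shape)
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    mask = _ellipsoid_mask(grid, spacing)

    # Background fractions with mild smooth spatial variation, renormalized.
    fractions = np.empty((4, *grid))
    for i, base in enumerate(config.background_fractions):
        fractions[i] = np.clip(base + _smooth_field(rng, grid, background_variation), 0.0, None)
    fractions /= fractions.sum(axis=0, keepdims=True)

    lesion_centers: list[np.ndarray] = []
    if truth.cspca_label == 1:
        center_vox, radius_mm = _place_lesion(mask, spacing, config, rng, max_lesion_attempts)
        lesion_centers.append(center_vox * spacing)
        idx = np.indices(grid).astype(float)
        coords = idx * spacing[:, None, None, None]
        d2 = sum((coords[a] - center_vox[a] * spacing[a]) ** 2 for a in range(3))
        inside = d2 <= radius_mm**2
        fractions[0][inside] *= config.lesion_c1_contrast
        fractions /= fractions.sum(axis=0, keepdims=True)

    s0 = np.full(grid, S0_REFERENCE)
    sigma = site.noise_sigma * S0_REFERENCE

    b_values = np.asarray(config.b_values, dtype=float)
    adcs = np.asarray(config.compartment_adcs, dtype=float)
    decay = np.exp(-np.outer(b_values, adcs))  # (n_b, 4)
    dwi: dict[float, np.ndarray] = {}
    for j, b in enumerate(b_values):
        clean = s0 * np.tensordot(decay[j], fractions, axes=(0, 0))
        dwi[float(b)] = _rician(clean, sigma, rng).astype(np.float32)

    # Deterministic smooth positive T2W field (radial profile) + Rician noise;
    # deterministic so that, at sigma=0, the in-mask median is identical across
    # patients and the biomarker separation property is exact.
    idx = np.indices(grid).astype(float)
    coords = idx * spacing[:, None, None, None]
    center_mm = (np.asarray(grid) - 1) * spacing / 2.0
    r2 = sum(((coords[a] - center_mm[a]) / (np.asarray(grid)[a] * spacing[a])) ** 2 for a in range(3))
    t2w_clean = S0_REFERENCE * (1.0 + 0.3 * np.exp(-4.0 * r2))
    t2w = _rician(t2w_clean, sigma, rng).astype(np.float32)

    truth.true_compartment_maps = fractions.astype(np.float32)
    truth.lesion_centers = lesion_centers

    affine = config.affine
    return ImagingStudy(
        patient_id=truth.patient_id,
        t2w=t2w,
        t2w_affine=affine,
        dwi={b: v for b, v in dwi.items()},
        dwi_affine=affine.copy(),
        prostate_mask=mask,
        mask_affine=affine.copy(),
        truth=truth,
    )


def _place_lesion(mask, spacing, config: CohortConfig, rng, max_attempts: int):
    """Pick a lesion center and radius such that the sphere lies inside the mask."""
    lo, hi = config.lesion_radius_range
    vox_in_mask = np.argwhere(mask > 0)
    for attempt in range(max_attempts):
        # Shrink the requested radius over attempts so small masks still work.
        shrink = 1.0 - 0.5 * attempt / max(1, max_attempts - 1)
        radius = rng.uniform(lo, hi) * shrink
        radius = max(radius, spacing.min())
        center = vox_in_mask[rng.integers(len(vox_in_mask))].astype(float)
        # sphere fits iff every voxel within the radius of the center is in-mask
        ball = _ball_offsets(radius, spacing)
        pts = np.round(center).astype(int) + ball
        if np.any(pts < 0) or np.any(pts >= np.asarray(mask.shape)):
            continue
        if np.all(mask[pts[:, 0], pts[:, 1], pts[:, 2]] > 0):
            return center, radius
    raise ConfigurationError(
        f"could not place a lesion of radius in {config.lesion_radius_range} mm inside the mask "
        f"after {max_attempts} attempts"
    )


def _ball_offsets(radius_mm: float, spacing) -> np.ndarray:
    r_vox = np.ceil(radius_mm / np.asarray(spacing)).astype(int)
    axes = [np.arange(-r, r + 1) for r in r_vox]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid * np.asarray(spacing)) ** 2).sum(axis=1)
    return grid[d2 <= radius_mm**2]


def synthesize_cohort_volumes(
    truths: Sequence[GroundTruth], config: CohortConfig
) -> list[ImagingStudy]:
    """Render volumes for every patient with a single per-cohort generator."""
    rng = np.random.default_rng(config.seed + 1)
    return [synthesize_patient_volumes(t, config, rng) for t in truths]


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------

def _nifti(arr: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)


def write_cohort(studies: Sequence[ImagingStudy], manifest: pd.DataFrame, out_dir) -> Path:
    """Write one NIfTI file per modality per patient plus the CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study in studies:
        nib.save(_nifti(study.t2w, study.t2w_affine), out / f"{study.patient_id}_t2w.nii.gz")
        nib.save(
            nib.Nifti1Image(study.prostate_mask.astype(np.uint8), study.mask_affine),
            out / f"{study.patient_id}_mask.nii.gz",
        )
        for b, vol in sorted(study.dwi.items()):
            nib.save(_nifti(vol, study.dwi_affine), out / f"{study.patient_id}_dwi_b{int(round(b))}.nii.gz")
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def read_cohort(cohort_dir) -> tuple[list[ImagingStudy], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortIOError` listing every patient with missing files.
    """
    d = Path(cohort_dir)
    manifest_path = d / "manifest.csv"
    if not manifest_path.exists():
        raise CohortIOError(f"no manifest.csv in {d}")
    manifest = pd.read_csv(manifest_path)
    studies: list[ImagingStudy] = []
    missing: list[str] = []
    for pid in manifest["patient_id"]:
        t2w_path = d / f"{pid}_t2w.nii.gz"
        mask_path = d / f"{pid}_mask.nii.gz"
        dwi_paths = sorted(d.glob(f"{pid}_dwi_b*.nii.gz"))
        if not t2w_path.exists() or not mask_path.exists() or not dwi_paths:
            missing.append(str(pid))
            continue
        t2w_img = nib.load(t2w_path)
        mask_img = nib.load(mask_path)
        dwi = {}
        dwi_affine = None
        for p in dwi_paths:
            b = float(p.name.rsplit("_dwi_b", 1)[1].split(".nii")[0])
            img = nib.load(p)
            dwi[b] = np.asarray(img.dataobj, dtype=np.float32)
            dwi_affine = img.affine
        studies.append(
            ImagingStudy(
                patient_id=str(pid),
                t2w=np.asarray(t2w_img.dataobj, dtype=np.float32),
                t2w_affine=t2w_img.affine,
                dwi=dict(sorted(dwi.items())),
                dwi_affine=dwi_affine,
                prostate_mask=(np.asarray(mask_img.dataobj) > 0.5).astype(np.uint8),
                mask_affine=mask_img.affine,
            )
        )
    if missing:
        raise CohortIOError(f"missing volume files for patients: {', '.join(missing)}")
    return studies, manifest
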