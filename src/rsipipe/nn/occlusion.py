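"""Occlusion sensitivity maps for trained classifiers.

Slides a patch over the volume, replaces it with the per-channel mean, and
records the drop in predicted csPCa probability; overlapping patch
contributions are averaged. Large positive values mark regions whose
occlusion lowers the predicted probability, i.e. regions the model relies on.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .train import TrainedClassifier, predict_proba

__all__ = ["occlusion_sensitivity"]


def occlusion_sensitivity(
    trained: TrainedClassifier,
    volume: np.ndarray,
    scalar: float | None = None,
    patch_size: int | tuple[int, int, int] = 8,
    stride: int | tuple[int, int, int] = 4,
) -> np.ndarray:
    """Map of (baseline probability - occluded probability) over a sliding grid.

    ``volume`` is a single (C, x, y, z) input. Returns an array with the input's
    spatial shape.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 4:
        raise ConfigurationError("volume must be (channel, x, y, z)")
    spatial = np.asarray(vol.shape[1:])
    patch = np.broadcast_to(np.asarray(patch_size, dtype=int), (3,)).copy()
    step = np.broadcast_to(np.asarray(stride, dtype=int), (3,)).copy()
    if np.any(step <= 0):
        raise ConfigurationError("stride must be positive")
    if np.any(patch > spatial):
        raise ConfigurationError("patch_size exceeds the volume size")

    scal = None if scalar is None else np.asarray([scalar], dtype=float)
    baseline = float(predict_proba(trained, vol[None], scal)[0])
    channel_mean = vol.reshape(vol.shape[0], -1).mean(axis=1)

    # Anchor grids per axis, always including the last valid start position.
    starts = []
    for a in range(3):
        s = list(range(0, spatial[a] - patch[a] + 1, step[a]))
        if s[-1] != spatial[a] - patch[a]:
            s.append(spatial[a] - patch[a])
        starts.append(s)

    accum = np.zeros(tuple(spatial))
    counts = np.zeros(tuple(spatial))
    occluded_batch = []
    slices = []
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (slice(i, i + patch[0]), slice(j, j + patch[1]), slice(k, k + patch[2]))
                occ = vol.copy()
                occ[(slice(None), *sl)] = channel_mean[:, None, None, None]
                occluded_batch.append(occ)
                slices.append(sl)

    probs = predict_proba(
        trained,
        np.stack(occluded_batch),
        None if scal is None else np.repeat(scal, len(occluded_batch)),
    )
    for sl, p in zip(slices, probs):
        accum[sl] += baseline - float(p)
        counts[sl] += 1.0
    return np.where(counts > 0, accum / np.maximum(counts, 1.0), 0.0)
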