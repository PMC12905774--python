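"""Restriction spectrum imaging (RSI) biomarker.

The multi-b-value DWI signal at each voxel is modeled as a linear combination
of exponential decays over four diffusion compartments with fixed diffusion
coefficients D1 < D2 < D3 < D4 (restricted, hindered, free, vascular):

    S(b) = sum_i c_i * exp(-b * D_i),      c_i >= 0.

Per-voxel coefficients are obtained by nonnegative least squares. The RSIrs
map is the restricted-compartment coefficient c1 normalized by the median T2W
signal inside the prostate mask; RSIrs_max, the patient-level biomarker, is
its maximum over the mask.

The nonnegative solver enumerates all 2^4 coefficient supports, solves the
unconstrained least-squares problem restricted to each support for every voxel
at once, and keeps the feasible solution with the smallest residual. For a
four-compartment design this is the exact NNLS optimum and is fully
vectorized over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ConfigurationError
from .cohort import DEFAULT_B_VALUES, DEFAULT_COMPARTMENT_ADCS

__all__ = [
    "RSIFitConfig",
    "CompartmentMaps",
    "RSIResult",
    "build_design_matrix",
    "fit_compartments",
    "compute_rsirs",
    "rsirs_max",
]


@dataclass(frozen=True)
class RSIFitConfig:
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    compartment_adcs: tuple[float, ...] = DEFAULT_COMPARTMENT_ADCS
    nonnegative: bool = True
    rsirs_scale: float = 1.0

    def validate(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        d = np.asarray(self.compartment_adcs, dtype=float)
        if b.ndim != 1 or np.any(np.diff(b) <= 0) or np.any(b < 0):
            raise ConfigurationError("b_values must be ascending and nonnegative")
        if d.ndim != 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ConfigurationError("compartment_adcs must be positive and strictly increasing")
        if b.size < d.size:
            raise ConfigurationError(
                f"need at least {d.size} b-values for a determined {d.size}-compartment fit"
            )
        if self.rsirs_scale <= 0:
            raise ConfigurationError("rsirs_scale must be positive")


@dataclass
class CompartmentMaps:
    """Per-voxel compartment signal coefficients and fit residual."""

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    c4: np.ndarray
    residual_rms: np.ndarray

    def stack(self) -> np.ndarray:
        return np.stack([self.c1, self.c2, self.c3, self.c4], axis=0)


@dataclass
class RSIResult:
    rsirs_map: np.ndarray
    rsirs_max: float
    t2w_median_in_mask: float


def build_design_matrix(b_values, compartment_adcs) -> np.ndarray:
    """Design matrix A with A[j, i] = exp(-b_j * D_i)."""
    cfg = RSIFitConfig(b_values=tuple(b_values), compartment_adcs=tuple(compartment_adcs))
    cfg.validate()
    b = np.asarray(b_values, dtype=float)
    d = np.asarray(compartment_adcs, dtype=float)
    return np.exp(-np.outer(b, d))


def _as_signal_matrix(dwi_stack, b_values) -> tuple[np.ndarray, tuple[int, ...]]:
    if isinstance(dwi_stack, dict):
        missing = [b for b in b_values if float(b) not in {float(k) for k in dwi_stack}]
        if missing:
            raise ConfigurationError(f"DWI stack missing b-values {missing}")
        lookup = {float(k): v for k, v in dwi_stack.items()}
        vols = [np.asarray(lookup[float(b)], dtype=float) for b in b_values]
    else:
        arr = np.asarray(dwi_stack, dtype=float)
        if arr.shape[0] != len(b_values):
            raise ConfigurationError("stacked DWI first axis must match b_values")
        vols = [arr[j] for j in range(arr.shape[0])]
    grid = vols[0].shape
    for v in vols:
        if v.shape != grid:
            raise ConfigurationError("all DWI volumes must share one grid")
    return np.stack([v.reshape(-1) for v in vols], axis=1), grid  # (n_vox, n_b)


def _nnls_all_supports(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Exact NNLS for a small design matrix, vectorized over rows of S.

    Enumerates every support of the 4 coefficients; for each, solves the
    restricted least-squares problem for all voxels in one matmul, then keeps
    the feasible (all-nonnegative) solution with minimal residual. The NNLS
    optimum coincides with the restricted LS solution on its own support, so
    it is always among the candidates.
    """
    n_vox, n_b = S.shape
    p = A.shape[1]
    best_res = np.einsum("ij,ij->i", S, S)  # empty support: x = 0
    best_x = np.zeros((n_vox, p))
    for k in range(1, p + 1):
        for support in combinations(range(p), k):
            A_s = A[:, support]
            pinv = np.linalg.pinv(A_s)  # (k, n_b)
            x_s = S @ pinv.T  # (n_vox, k)
            resid = S - x_s @ A_s.T
            res = np.einsum("ij,ij->i", resid, resid)
            feasible = np.all(x_s >= -1e-12, axis=1)
            better = feasible & (res < best_res - 1e-12 * np.maximum(best_res, 1.0))
            if np.any(better):
                best_res[better] = res[better]
                best_x[better] = 0.0
                cols = np.asarray(support)
                best_x[np.ix_(better, cols)] = np.clip(x_s[better], 0.0, None)
    return np.concatenate([best_x, best_res[:, None]], axis=1)


def fit_compartments(
    dwi_stack,
    fit_config: RSIFitConfig,
    mask: np.ndarray | None = None,
) -> CompartmentMaps:
    """Per-voxel least-squares fit of the four-compartment decay model.

    ``dwi_stack`` is either a mapping {b-value: volume} or an array with the
    b-value axis first. With ``nonnegative=True`` (default) coefficients are
    the exact NNLS solution; otherwise plain least squares. Voxels outside an
    optional mask are set to zero without being fit.
    """
    fit_config.validate()
    A = build_design_matrix(fit_config.b_values, fit_config.compartment_adcs)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ConfigurationError("rank-deficient design matrix (duplicate D or too few b-values)")
    S, grid = _as_signal_matrix(dwi_stack, fit_config.b_values)

    if mask is not None:
        if mask.shape != grid:
            raise ConfigurationError("mask grid does not match DWI grid")
        sel = mask.reshape(-1) > 0
    else:
        sel = np.ones(S.shape[0], dtype=bool)

    n_vox = S.shape[0]
    coef = np.zeros((n_vox, 4))
    res = np.zeros(n_vox)
    if np.any(sel):
        S_sel = S[sel]
        if fit_config.nonnegative:
            out = _nnls_all_supports(A, S_sel)
            coef[sel] = out[:, :4]
            res[sel] = out[:, 4]
        else:
            x, residuals, *_ = np.linalg.lstsq(A, S_sel.T, rcond=None)
            coef[sel] = x.T
            r = S_sel - coef[sel] @ A.T
            res[sel] = np.einsum("ij,ij->i", r, r)
    rms = np.sqrt(np.maximum(res, 0.0) / len(fit_config.b_values))
    return CompartmentMaps(
        c1=coef[:, 0].reshape(grid),
        c2=coef[:, 1].reshape(grid),
        c3=coef[:, 2].reshape(grid),
        c4=coef[:, 3].reshape(grid),
        residual_rms=rms.reshape(grid),
    )


def compute_rsirs(
    c1_map: np.ndarray,
    t2w_volume: np.ndarray,
    prostate_mask: np.ndarray,
    rsirs_scale: float = 1.0,
) -> RSIResult:
    """RSIrs map: c1 normalized by the median T2W signal inside the mask.

    Defined on every voxel; the patient-level biomarker ``rsirs_max`` is the
    maximum over mask voxels.
    """
    if c1_map.shape != t2w_volume.shape or c1_map.shape != prostate_mask.shape:
        raise ConfigurationError("c1, T2W and mask must share one grid")
    in_mask = prostate_mask > 0
    if not np.any(in_mask):
        raise ConfigurationError("empty prostate mask")
    med = float(np.median(t2w_volume[in_mask]))
    if med <= 0:
        raise ConfigurationError(f"nonpositive T2W median in mask ({med})")
    rs_map = (rsirs_scale * c1_map / med).astype(np.float64)
    return RSIResult(
        rsirs_map=rs_map,
        rsirs_max=rsirs_max(rs_map, prostate_mask),
        t2w_median_in_mask=med,
    )


def rsirs_max(rsirs_map: np.ndarray, prostate_mask: np.ndarray) -> float:
    """Maximum of the RSIrs map over prostate-mask voxels."""
    in_mask = prostate_mask > 0
    if not np.any(in_mask):
        raise ConfigurationError("empty prostate mask")
    return float(np.max(rsirs_map[in_mask]))
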