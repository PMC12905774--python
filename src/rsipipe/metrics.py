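"""Evaluation statistics for patient-level csPCa detection.

AUC (tie-corrected Mann–Whitney), average precision, the operating threshold
and specificity at a fixed sensitivity, continuous (category-free) NRI, IDI,
Brier score, calibration bins, decision-curve net benefit, confusion counts,
percentile-bootstrap confidence intervals and paired-difference p-values,
Bonferroni adjustment, and Cochran's Q / I-squared heterogeneity across sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError

__all__ = [
    "roc_auc",
    "average_precision",
    "threshold_at_sensitivity",
    "nri",
    "idi",
    "brier",
    "calibration_bins",
    "net_benefit",
    "confusion_at_threshold",
    "bootstrap_eval",
    "BootstrapResult",
    "bonferroni_alpha",
    "cochran_i2",
    "ForestResult",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0, 1])):
        raise ConfigurationError("labels must be binary 0/1")
    if classes.size < 2:
        raise ConfigurationError("both classes must be present")
    return y.astype(int)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve as the tie-corrected Mann–Whitney statistic.

    Tied score pairs count one half, i.e. the probability that a random event
    outranks a random nonevent with ties split.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Step-wise average precision over the descending-score sweep."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise ConfigurationError("average precision needs at least one event")
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    # sweep over distinct thresholds: keep the last index of each tied run
    last_of_run = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    p = precision[last_of_run]
    r = recall[last_of_run]
    dr = np.diff(np.r_[0.0, r])
    return float(np.sum(p * dr))


def threshold_at_sensitivity(scores, labels, target: float = 0.90) -> tuple[float, float]:
    """Largest threshold (positive call when score >= threshold) achieving
    sensitivity >= target, and the specificity at that threshold.

    Works identically for discrete (e.g. PI-RADS) and continuous scores.
    """
    if not 0 < target <= 1:
        raise ConfigurationError("target sensitivity must be in (0, 1]")
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise ConfigurationError("needs at least one event")
    s = np.asarray(scores, dtype=float)
    candidates = np.unique(s)[::-1]  # descending
    for c in candidates:
        call = s >= c
        sens = (call & (y == 1)).sum() / y.sum()
        if sens >= target:
            neg = (y == 0)
            spec = float(((~call) & neg).sum() / neg.sum()) if neg.sum() else float("nan")
            return float(c), spec
    # unreachable: the smallest score calls everyone positive (sensitivity 1)
    raise AssertionError("no threshold achieved the target sensitivity")


def nri(p_new, p_old, labels) -> float:
    """Continuous (category-free) net reclassification improvement.

    [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)];
    ties contribute zero. Range [-2, 2].
    """
    y = _check_binary(labels)
    new = np.asarray(p_new, dtype=float)
    old = np.asarray(p_old, dtype=float)
    up = new > old
    down = new < old
    ev = y == 1
    ne = ~ev
    event_term = (up[ev].mean() - down[ev].mean()) if ev.any() else 0.0
    nonevent_term = (down[ne].mean() - up[ne].mean()) if ne.any() else 0.0
    return float(event_term + nonevent_term)


def idi(p_new, p_old, labels) -> float:
    """Integrated discrimination improvement: the change in discrimination
    slope (mean probability in events minus nonevents) from old to new."""
    y = _check_binary(labels)
    new = np.asarray(p_new, dtype=float)
    old = np.asarray(p_old, dtype=float)
    ev = y == 1
    slope_new = new[ev].mean() - new[~ev].mean()
    slope_old = old[ev].mean() - old[~ev].mean()
    return float(slope_new - slope_old)


def brier(probabilities, labels) -> float:
    """Mean squared error between predicted probability and binary outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ConfigurationError("empty input")
    return float(np.mean((p - y) ** 2))


def calibration_bins(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins with mean prediction, observed rate, count."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ConfigurationError("empty input")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append({
            "bin": b,
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "mean_predicted": float(p[sel].mean()) if sel.any() else np.nan,
            "observed_rate": float(y[sel].mean()) if sel.any() else np.nan,
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def net_benefit(probabilities, labels, threshold_grid) -> pd.DataFrame:
    """Decision-curve net benefit NB(pt) = TP/n - (FP/n) * pt / (1 - pt).

    Positive call when probability >= pt; thresholds equal to 1 are excluded.
    Also emits treat-all and treat-none reference columns.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in np.asarray(threshold_grid, dtype=float):
        if not 0 < pt < 1:
            continue
        call = p >= pt
        tp = int((call & (y == 1)).sum())
        fp = int((call & (y == 0)).sum())
        w = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp / n - (fp / n) * w,
            "treat_all": prevalence - (1 - prevalence) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def confusion_at_threshold(scores, labels, threshold: float) -> dict[str, int]:
    """TP/FP/TN/FN with positive call when score >= threshold."""
    if not np.isfinite(threshold):
        raise ConfigurationError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    call = s >= threshold
    return {
        "tp": int((call & (y == 1)).sum()),
        "fp": int((call & (y == 0)).sum()),
        "tn": int((~call & (y == 0)).sum()),
        "fn": int((~call & (y == 1)).sum()),
    }


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    point: dict[str, float]
    samples: pd.DataFrame  # one row per bootstrap resample
    ci: dict[str, tuple[float, float]]
    bootstrap_median: dict[str, float]
    n_boot: int
    n_redrawn: int

    def p_value(self, key: str) -> float:
        """Two-sided percentile p-value that the bootstrapped quantity differs
        from zero, floored at 2 / n_boot."""
        x = self.samples[key].to_numpy()
        frac_le = np.mean(x <= 0)
        frac_ge = np.mean(x >= 0)
        return float(max(2 * min(frac_le, frac_ge), 2 / self.n_boot))


def bootstrap_eval(
    table: pd.DataFrame,
    metric_fn: Callable[[pd.DataFrame], Mapping[str, float] | float],
    n_boot: int = 10000,
    seed: int = 0,
    clustering: str = "none",
    label_column: str = "cspca_label",
    ci_level: float = 0.95,
    max_consecutive_redraws: int = 1000,
) -> BootstrapResult:
    """Percentile bootstrap of any table-level metric.

    Patients are resampled with replacement — freely (``clustering='none'``)
    or within site strata (``clustering='by_site'``, preserving per-site
    sample sizes). Every metric is recomputed inside each resample; CIs are
    the 2.5th/97.5th percentiles at the default level. Resamples that lose a
    label class are redrawn (counted, capped). Deterministic under ``seed``.
    """
    if clustering not in ("none", "by_site"):
        raise ConfigurationError("clustering must be 'none' or 'by_site'")
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    n = len(table)
    point_raw = metric_fn(table)
    point = dict(point_raw) if isinstance(point_raw, Mapping) else {"value": float(point_raw)}

    site_groups = None
    if clustering == "by_site":
        site_groups = [g.index.to_numpy() for _, g in table.groupby("site_id")]

    labels = table[label_column].to_numpy()
    rows = []
    n_redrawn = 0
    for _ in range(n_boot):
        for attempt in range(max_consecutive_redraws):
            if site_groups is None:
                idx = rng.integers(0, n, n)
            else:
                idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in site_groups])
            if len(np.unique(labels[idx])) == 2:
                break
            n_redrawn += 1
        else:
            raise ConfigurationError("could not draw a two-class bootstrap resample")
        res = metric_fn(table.iloc[idx])
        rows.append(dict(res) if isinstance(res, Mapping) else {"value": float(res)})
    samples = pd.DataFrame(rows)
    alpha = (1 - ci_level) / 2
    ci = {
        k: (
            float(np.percentile(samples[k], 100 * alpha)),
            float(np.percentile(samples[k], 100 * (1 - alpha))),
        )
        for k in samples.columns
    }
    med = {k: float(np.median(samples[k])) for k in samples.columns}
    return BootstrapResult(point=point, samples=samples, ci=ci,
                           bootstrap_median=med, n_boot=n_boot, n_redrawn=n_redrawn)


def bonferroni_alpha(alpha: float = 0.05, m: int = 7) -> tuple[float, float]:
    """Adjusted significance threshold alpha/m, raw and rounded to 3 decimals."""
    if m < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    raw = alpha / m
    return raw, round(raw, 3)


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class ForestResult:
    site_ids: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    ns: np.ndarray | None
    pooled: float
    cochran_q: float
    i_squared: float  # percentage in [0, 100]


def cochran_i2(estimates, standard_errors, site_ids=None, ns=None) -> ForestResult:
    """Fixed-effect inverse-variance pooling with Cochran's Q and I-squared.

    I^2 = max(0, (Q - (k - 1)) / Q) * 100.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if est.size < 2:
        raise ConfigurationError("heterogeneity needs at least 2 sites")
    if np.any(se <= 0):
        raise ConfigurationError("standard errors must be positive (zero SE is degenerate)")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    q = float(np.sum(w * (est - pooled) ** 2))
    k = est.size
    i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    i2 = min(i2, 100.0)
    return ForestResult(
        site_ids=list(site_ids) if site_ids is not None else [str(i) for i in range(k)],
        estimates=est,
        standard_errors=se,
        ns=None if ns is None else np.asarray(ns),
        pooled=pooled,
        cochran_q=q,
        i_squared=i2,
    )
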