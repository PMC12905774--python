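"""Leave-one-center-out (LOCO) evaluation.

Each rotatable imaging center is held out once: the RSI biomarker is computed
per patient, both 3D dense classifiers are trained on the remaining centers
(with a stratified internal validation split used only for best-epoch
selection), the logistic fusion models are fit on the training folds only,
and the held-out center is scored. Aggregated predictions — each patient
scored exactly once — are restricted to the biopsy-naïve, biopsy-confirmed
(BN-BC) subset and summarized with the full statistics suite: AUC, average
precision, specificity at fixed sensitivity, ΔSpec/NRI/IDI against the
PI-RADS reference, Brier score, percentile-bootstrap CIs and p-values,
Bonferroni adjustment, and per-site forest heterogeneity (Cochran's Q, I²).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cohort import COHORT_FLAG_BNBC
from .errors import ConfigurationError, LeakageError
from .fusion import MODEL_ROSTER, FusionSpec, run_model_roster
from .metrics import (
    BootstrapResult,
    ForestResult,
    bonferroni_alpha,
    bootstrap_eval,
    brier,
    cochran_i2,
    roc_auc,
    average_precision,
    threshold_at_sensitivity,
    nri,
    idi,
)
from .nn import DenseNetConfig, TrainConfig, predict_proba, train_classifier
from .prep import (
    AugmentPolicy,
    BPMRI_CHANNELS,
    BPMRI_RSI_CHANNELS,
    ImagingStudy,
    assemble_input,
    compute_adc,
    resample_to_t2w,
    select_high_b,
)
from .rsi import RSIFitConfig, compute_rsirs, fit_compartments

__all__ = [
    "LocoConfig",
    "PatientFeatures",
    "prepare_patient_features",
    "loco_split",
    "rotatable_sites",
    "run_loco_evaluation",
    "compute_metric_report",
    "forest_by_site",
    "MetricReport",
    "LocoResult",
]


@dataclass(frozen=True)
class LocoConfig:
    fit_config: RSIFitConfig = field(default_factory=RSIFitConfig)
    train_config: TrainConfig = field(default_factory=lambda: TrainConfig(total_epochs=8, batch_size=8))
    net_preset: str = "tiny"  # or "full"
    crop_shape: tuple[int, int, int] = (16, 16, 12)
    always_train: tuple[str, ...] | str | None = "smallest"
    sensitivity_target: float = 0.90
    reference_model: int = 1
    n_boot: int = 1000
    seed: int = 0
    clustering: str = "none"
    alpha: float = 0.05
    n_comparisons: int = 7
    val_fraction: float = 0.10
    augment_policy: AugmentPolicy | None = None


@dataclass
class PatientFeatures:
    patient_id: str
    bpmri: np.ndarray  # (3, x, y, z)
    bpmri_rsi: np.ndarray  # (5, x, y, z)
    rsirs_max: float


def prepare_patient_features(
    studies: Sequence[ImagingStudy],
    fit_config: RSIFitConfig,
    crop_shape: tuple[int, int, int],
) -> dict[str, PatientFeatures]:
    """Resample, derive ADC/high-b, fit the RSI compartments and build both
    classifier input tensors for every patient."""
    out: dict[str, PatientFeatures] = {}
    for study in studies:
        study = resample_to_t2w(study)
        study.adc = compute_adc(study.dwi)
        study.high_b = select_high_b(study.dwi)
        maps = fit_compartments(study.dwi, fit_config, mask=study.prostate_mask)
        rsirs = compute_rsirs(maps.c1, study.t2w, study.prostate_mask, fit_config.rsirs_scale)
        rsi_maps = {"rsi_c1": maps.c1, "rsi_c2": maps.c2}
        bpmri = assemble_input(study, None, BPMRI_CHANNELS, crop_shape)
        bpmri_rsi = assemble_input(study, rsi_maps, BPMRI_RSI_CHANNELS, crop_shape,
                                   rsirs_max=rsirs.rsirs_max)
        out[study.patient_id] = PatientFeatures(
            patient_id=study.patient_id,
            bpmri=bpmri.array,
            bpmri_rsi=bpmri_rsi.array,
            rsirs_max=rsirs.rsirs_max,
        )
    return out


def rotatable_sites(manifest: pd.DataFrame, always_train: tuple[str, ...] | str | None):
    """Resolve the always-train policy into (rotatable, always-train) site lists.

    ``'smallest'`` keeps the smallest center permanently in the training split
    (a center with a handful of patients cannot serve as a validation site)
    whenever there are more than two sites; an explicit tuple names the
    always-train sites.
    """
    counts = manifest.groupby("site_id").size().sort_values()
    sites = list(counts.index)
    if always_train is None or always_train == ():
        always = []
    elif always_train == "smallest":
        always = [counts.index[0]] if len(sites) > 2 else []
    else:
        always = list(always_train)
        unknown = set(always) - set(sites)
        if unknown:
            raise ConfigurationError(f"unknown always-train sites: {sorted(unknown)}")
    return [s for s in sites if s not in always], always


def loco_split(
    manifest: pd.DataFrame,
    holdout_site: str,
    seed: int = 0,
    always_train: tuple[str, ...] = (),
    val_fraction: float = 0.10,
) -> tuple[list[str], list[str], list[str]]:
    """Partition patient ids into (train, internal-val, test) for one rotation.

    Test is every patient of the held-out site; internal-val is a stratified
    ``val_fraction`` of the remaining patients matched by csPCa label; train is
    the rest. The three sets are disjoint and cover the cohort.
    """
    if holdout_site in always_train:
        raise ConfigurationError(f"site {holdout_site} is designated always-train")
    if holdout_site not in set(manifest["site_id"]):
        raise ConfigurationError(f"unknown holdout site {holdout_site}")
    test = manifest.loc[manifest["site_id"] == holdout_site, "patient_id"].tolist()
    pool = manifest.loc[manifest["site_id"] != holdout_site]
    tr_ids, val_ids = train_test_split(
        pool["patient_id"].to_numpy(),
        test_size=val_fraction,
        stratify=pool["cspca_label"].to_numpy(),
        random_state=seed % (2**32),
    )
    return list(tr_ids), list(val_ids), test


# ---------------------------------------------------------------------------
# Metric report
# ---------------------------------------------------------------------------

METRIC_KEYS = ("auc", "average_precision", "threshold_at_sens090",
               "specificity_at_sens090", "delta_spec_vs_reference",
               "nri_vs_reference", "idi_vs_reference", "brier")


@dataclass
class MetricReport:
    """Per-model evaluation results with bootstrap CIs (machine twin of the
    published per-model performance table)."""

    entries: pd.DataFrame  # rows: model, metric, point, bootstrap_median, ci_low, ci_high
    p_values_auc_vs_reference: dict[int, float]
    reference_model: int
    bonferroni_alpha: float
    bonferroni_alpha_rounded: float
    n_patients: int
    n_boot: int
    bootstrap: BootstrapResult | None = None

    def lookup(self, model_id: int, metric: str) -> tuple[float, float, float]:
        row = self.entries[(self.entries["model"] == model_id) & (self.entries["metric"] == metric)]
        if row.empty:
            raise KeyError((model_id, metric))
        r = row.iloc[0]
        return float(r["point"]), float(r["ci_low"]), float(r["ci_high"])


def _model_metrics(df: pd.DataFrame, model_ids, reference: int, target: float) -> dict[str, float]:
    y = df["cspca_label"].to_numpy()
    out: dict[str, float] = {}
    ref_scores = df[f"model{reference}"].to_numpy(dtype=float)
    _, ref_spec = threshold_at_sensitivity(ref_scores, y, target)
    for m in model_ids:
        s = df[f"model{m}"].to_numpy(dtype=float)
        out[f"auc_{m}"] = roc_auc(s, y)
        out[f"average_precision_{m}"] = average_precision(s, y)
        thr, spec = threshold_at_sensitivity(s, y, target)
        out[f"threshold_at_sens090_{m}"] = thr
        out[f"specificity_at_sens090_{m}"] = spec
        out[f"delta_spec_vs_reference_{m}"] = spec - ref_spec
        out[f"nri_vs_reference_{m}"] = nri(s, ref_scores, y)
        out[f"idi_vs_reference_{m}"] = idi(s, ref_scores, y)
        out[f"brier_{m}"] = brier(s, y)
        out[f"dauc_{m}"] = out[f"auc_{m}"] - roc_auc(ref_scores, y)
    return out


def compute_metric_report(
    table: pd.DataFrame,
    model_ids: Sequence[int] = tuple(MODEL_ROSTER),
    reference: int = 1,
    sensitivity_target: float = 0.90,
    n_boot: int = 10000,
    seed: int = 0,
    clustering: str = "none",
    alpha: float = 0.05,
    n_comparisons: int = 7,
) -> MetricReport:
    """Full-table metrics with percentile-bootstrap CIs for every model.

    Every metric — including the operating threshold at the target
    sensitivity — is re-derived inside each bootstrap resample. Point
    estimates report the bootstrap median (primary, as in the published
    table) alongside the full-sample value.
    """
    boot = bootstrap_eval(
        table,
        lambda df: _model_metrics(df, model_ids, reference, sensitivity_target),
        n_boot=n_boot,
        seed=seed,
        clustering=clustering,
    )
    rows = []
    for m in model_ids:
        for metric in METRIC_KEYS:
            key = f"{metric}_{m}"
            lo, hi = boot.ci[key]
            rows.append({
                "model": m,
                "metric": metric,
                "point": boot.bootstrap_median[key],
                "full_sample": boot.point[key],
                "ci_low": lo,
                "ci_high": hi,
            })
    p_values = {m: boot.p_value(f"dauc_{m}") for m in model_ids if m != reference}
    raw, rounded = bonferroni_alpha(alpha, n_comparisons)
    return MetricReport(
        entries=pd.DataFrame(rows),
        p_values_auc_vs_reference=p_values,
        reference_model=reference,
        bonferroni_alpha=raw,
        bonferroni_alpha_rounded=rounded,
        n_patients=len(table),
        n_boot=n_boot,
        bootstrap=boot,
    )


def forest_by_site(
    table: pd.DataFrame,
    model_id: int,
    metric: str = "auc",
    sensitivity_target: float = 0.90,
    n_boot: int = 1000,
    seed: int = 0,
) -> ForestResult:
    """Per-site estimates with bootstrap SEs pooled by inverse variance.

    Sites whose BN-BC subset lacks one of the classes are excluded (the
    statistic is undefined there).
    """
    ests, ses, ids, ns = [], [], [], []
    rng = np.random.default_rng(seed)
    for site, g in table.groupby("site_id"):
        y = g["cspca_label"].to_numpy()
        s = g[f"model{model_id}"].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            continue

        def stat(scores, labels):
            if metric == "auc":
                return roc_auc(scores, labels)
            return threshold_at_sensitivity(scores, labels, sensitivity_target)[1]

        samples = []
        n = len(y)
        for _ in range(n_boot):
            for _attempt in range(1000):
                idx = rng.integers(0, n, n)
                if len(np.unique(y[idx])) == 2:
                    break
            samples.append(stat(s[idx], y[idx]))
        se = float(np.std(samples, ddof=1))
        if se <= 0:
            se = 1e-6  # degenerate site (constant statistic): near-zero variance
        ests.append(stat(s, y))
        ses.append(se)
        ids.append(site)
        ns.append(n)
    if len(ests) < 2:
        raise ConfigurationError("need at least 2 sites with both classes for a forest plot")
    return cochran_i2(ests, ses, site_ids=ids, ns=ns)


# ---------------------------------------------------------------------------
# Full LOCO run
# ---------------------------------------------------------------------------

@dataclass
class LocoResult:
    prediction_table: pd.DataFrame
    report: MetricReport
    forests: dict[str, dict[int, ForestResult]]
    fusion_specs: dict[str, dict[int, FusionSpec]]  # per held-out site
    fold_summary: pd.DataFrame


def run_loco_evaluation(
    studies: Sequence[ImagingStudy],
    manifest: pd.DataFrame,
    cfg: LocoConfig,
) -> LocoResult:
    """Run the complete leave-one-center-out evaluation on an in-memory cohort."""
    features = prepare_patient_features(studies, cfg.fit_config, cfg.crop_shape)
    missing = set(manifest["patient_id"]) - set(features)
    if missing:
        raise ConfigurationError(f"no imaging for patients: {sorted(missing)[:5]}...")
    manifest = manifest.reset_index(drop=True)
    rot, always = rotatable_sites(manifest, cfg.always_train)

    if cfg.net_preset == "tiny":
        net3 = DenseNetConfig.tiny(in_channels=3)
        net5 = DenseNetConfig.tiny(in_channels=5, scalar_fusion=True)
    elif cfg.net_preset == "full":
        net3 = DenseNetConfig.full(in_channels=3)
        net5 = DenseNetConfig.full(in_channels=5, scalar_fusion=True)
    else:
        raise ConfigurationError(f"unknown net preset {cfg.net_preset}")

    by_id = manifest.set_index("patient_id")
    all_rows = []
    fold_rows = []
    fusion_specs: dict[str, dict[int, FusionSpec]] = {}
    for fold_i, site in enumerate(rot):
        fold_seed = cfg.seed * 1009 + fold_i
        tr_ids, val_ids, te_ids = loco_split(
            manifest, site, seed=fold_seed, always_train=tuple(always),
            val_fraction=cfg.val_fraction,
        )
        pool_ids = tr_ids + val_ids
        if set(pool_ids) & set(te_ids):
            raise LeakageError(f"fold {site}: training pool overlaps the held-out site")

        def tensors(ids, key):
            return np.stack([getattr(features[p], key) for p in ids])

        pool_labels = by_id.loc[pool_ids, "cspca_label"].to_numpy()
        val_indices = np.arange(len(tr_ids), len(pool_ids))
        pool_scalars = np.array([features[p].rsirs_max for p in pool_ids])

        tcfg = dataclasses.replace(cfg.train_config, seed=fold_seed)
        trained3 = train_classifier(
            tensors(pool_ids, "bpmri"), None, pool_labels, net3, tcfg,
            augment_policy=cfg.augment_policy, val_indices=val_indices,
        )
        trained5 = train_classifier(
            tensors(pool_ids, "bpmri_rsi"), pool_scalars, pool_labels, net5, tcfg,
            augment_policy=cfg.augment_policy, val_indices=val_indices,
        )

        def feature_frame(ids):
            f = pd.DataFrame({
                "patient_id": ids,
                "site_id": by_id.loc[ids, "site_id"].to_numpy(),
                "pirads": by_id.loc[ids, "pirads"].to_numpy(dtype=float),
                "rsirs_max": [features[p].rsirs_max for p in ids],
            })
            f["dl_bpmri_prob"] = predict_proba(trained3, tensors(ids, "bpmri"))
            f["dl_bpmri_rsi_prob"] = predict_proba(
                trained5, tensors(ids, "bpmri_rsi"),
                np.array([features[p].rsirs_max for p in ids]),
            )
            return f

        train_f = feature_frame(pool_ids)
        test_f = feature_frame(te_ids)
        scores, specs = run_model_roster(train_f, pool_labels, test_f, holdout_site=site)
        fusion_specs[site] = specs

        fold_table = pd.DataFrame({
            "patient_id": te_ids,
            "site_id": by_id.loc[te_ids, "site_id"].to_numpy(),
            "cohort_flag": by_id.loc[te_ids, "cohort_flag"].to_numpy(),
            "cspca_label": by_id.loc[te_ids, "cspca_label"].to_numpy(),
            "pirads": by_id.loc[te_ids, "pirads"].to_numpy(),
            "rsirs_max": [features[p].rsirs_max for p in te_ids],
        })
        for m in MODEL_ROSTER:
            fold_table[f"model{m}"] = scores[f"model{m}"].to_numpy()
        all_rows.append(fold_table)
        fold_rows.append({
            "holdout_site": site,
            "n_train": len(tr_ids),
            "n_val": len(val_ids),
            "n_test": len(te_ids),
            "best_epoch_bpmri": trained3.best_epoch,
            "best_epoch_bpmri_rsi": trained5.best_epoch,
        })

    prediction_table = pd.concat(all_rows, ignore_index=True)
    if prediction_table["patient_id"].duplicated().any():
        raise LeakageError("a patient was predicted more than once across folds")

    bnbc = prediction_table[prediction_table["cohort_flag"] == COHORT_FLAG_BNBC].reset_index(drop=True)
    report = compute_metric_report(
        bnbc,
        reference=cfg.reference_model,
        sensitivity_target=cfg.sensitivity_target,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        clustering=cfg.clustering,
        alpha=cfg.alpha,
        n_comparisons=cfg.n_comparisons,
    )
    forests: dict[str, dict[int, ForestResult]] = {"auc": {}, "specificity": {}}
    if bnbc["site_id"].nunique() >= 2:
        for m in MODEL_ROSTER:
            for metric in ("auc", "specificity"):
                try:
                    forests[metric][m] = forest_by_site(
                        bnbc, m, metric="auc" if metric == "auc" else "spec",
                        sensitivity_target=cfg.sensitivity_target,
                        n_boot=min(cfg.n_boot, 500), seed=cfg.seed + m,
                    )
                except ConfigurationError:
                    continue
    return LocoResult(
        prediction_table=prediction_table,
        report=report,
        forests=forests,
        fusion_specs=fusion_specs,
        fold_summary=pd.DataFrame(fold_rows),
    )
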