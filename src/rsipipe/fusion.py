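"""Logistic fusion of PI-RADS, RSIrs_max and deep-learning probabilities.

The seven-model roster: (1) PI-RADS alone, (2) RSIrs_max alone — univariable
logistic scores; (3) the bpMRI CNN and (4) the bpMRI+RSI CNN — raw network
probabilities; (5) PI-RADS + RSIrs_max, (6) PI-RADS + bpMRI CNN probability,
(7) PI-RADS + bpMRI+RSI CNN probability — multivariable logistic fusions.
PI-RADS enters as a numeric 1–5 covariate. Fusion coefficients are fit only
on training-fold patients; a leakage guard rejects any attempt to fit on
patients from the current held-out site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, LeakageError

__all__ = ["MODEL_ROSTER", "FusionSpec", "fit_logistic", "predict_fused", "run_model_roster"]

MODEL_ROSTER: dict[int, tuple[str, ...]] = {
    1: ("pirads",),
    2: ("rsirs_max",),
    3: ("dl_bpmri_prob",),
    4: ("dl_bpmri_rsi_prob",),
    5: ("pirads", "rsirs_max"),
    6: ("pirads", "dl_bpmri_prob"),
    7: ("pirads", "dl_bpmri_rsi_prob"),
}

# Models whose score is a fitted logistic combination (3 and 4 are raw CNN
# output probabilities, passed through unchanged).
LOGISTIC_MODELS = (1, 2, 5, 6, 7)

_PROB_EPS = 1e-9
_SEPARATION_C = 10.0  # weak-L2 fallback strength (sklearn C) under separation


@dataclass
class FusionSpec:
    model_id: int
    feature_list: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    coefficient_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    intercept_ci: tuple[float, float] = (np.nan, np.nan)
    converged: bool = True
    separation_fallback: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "feature_list": list(self.feature_list),
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "coefficient_cis": {k: list(v) for k, v in self.coefficient_cis.items()},
                "intercept_ci": list(self.intercept_ci),
                "converged": self.converged,
                "separation_fallback": self.separation_fallback,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FusionSpec":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            feature_list=tuple(d["feature_list"]),
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            coefficient_cis={k: tuple(v) for k, v in d["coefficient_cis"].items()},
            intercept_ci=tuple(d["intercept_ci"]),
            converged=d["converged"],
            separation_fallback=d["separation_fallback"],
        )


def fit_logistic(features: pd.DataFrame, labels, model_id: int = 0) -> FusionSpec:
    """Unpenalized maximum-likelihood logistic regression with Wald 95% CIs.

    Under (quasi-)perfect separation the fit falls back to a weakly L2
    penalized solution and flags the spec (``separation_fallback``).
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("logistic fit requires both classes")
    if features.isna().any().any():
        raise ConfigurationError("missing feature values")
    feature_list = tuple(features.columns)
    X = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")

    params = bse = None
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params, bse = res.params, res.bse
        # Treat exploded coefficients / non-identified fits as separation.
        if not converged or not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 1e3:
            params = None
    except Exception:
        params = None

    if params is None:
        lr = LogisticRegression(C=_SEPARATION_C, solver="lbfgs", max_iter=1000)
        lr.fit(features.to_numpy(dtype=float), y)
        intercept = float(lr.intercept_[0])
        coefs = {f: float(c) for f, c in zip(feature_list, lr.coef_[0])}
        return FusionSpec(
            model_id=model_id,
            feature_list=feature_list,
            intercept=intercept,
            coefficients=coefs,
            converged=False,
            separation_fallback=True,
        )

    z = 1.959963984540054
    cis = {
        f: (float(params[i + 1] - z * bse[i + 1]), float(params[i + 1] + z * bse[i + 1]))
        for i, f in enumerate(feature_list)
    }
    return FusionSpec(
        model_id=model_id,
        feature_list=feature_list,
        intercept=float(params[0]),
        coefficients={f: float(params[i + 1]) for i, f in enumerate(feature_list)},
        coefficient_cis=cis,
        intercept_ci=(float(params[0] - z * bse[0]), float(params[0] + z * bse[0])),
        converged=converged,
    )


def predict_fused(spec: FusionSpec, features: pd.DataFrame) -> np.ndarray:
    """sigmoid(intercept + sum beta * x) per row, bounded away from 0 and 1."""
    missing = [f for f in spec.feature_list if f not in features.columns]
    if missing:
        raise ConfigurationError(f"missing features: {missing}")
    logit = spec.intercept + sum(
        spec.coefficients[f] * features[f].to_numpy(dtype=float) for f in spec.feature_list
    )
    p = 1.0 / (1.0 + np.exp(-np.asarray(logit, dtype=float)))
    return np.clip(p, _PROB_EPS, 1 - _PROB_EPS)


def run_model_roster(
    train_features: pd.DataFrame,
    train_labels,
    test_features: pd.DataFrame,
    holdout_site: str | None = None,
) -> tuple[pd.DataFrame, dict[int, FusionSpec]]:
    """Score the seven-model roster on the test fold.

    ``train_features``/``test_features`` need columns pirads, rsirs_max,
    dl_bpmri_prob, dl_bpmri_rsi_prob (and site_id when a leakage guard site
    is given). Models 1, 2, 5, 6, 7 are logistic fits on the training fold;
    models 3 and 4 pass the CNN probabilities through unchanged.
    """
    required = {"pirads", "rsirs_max", "dl_bpmri_prob", "dl_bpmri_rsi_prob"}
    for name, df in (("train", train_features), ("test", test_features)):
        miss = required - set(df.columns)
        if miss:
            raise ConfigurationError(f"{name} features missing columns: {sorted(miss)}")
    if holdout_site is not None:
        if "site_id" not in train_features.columns:
            raise ConfigurationError("leakage guard requires a site_id column")
        if (train_features["site_id"] == holdout_site).any():
            raise LeakageError(
                f"fusion fit attempted on patients from held-out site {holdout_site}"
            )

    scores = pd.DataFrame(index=test_features.index)
    specs: dict[int, FusionSpec] = {}
    for model_id, feats in MODEL_ROSTER.items():
        if model_id in LOGISTIC_MODELS:
            spec = fit_logistic(train_features[list(feats)], train_labels, model_id=model_id)
            specs[model_id] = spec
            scores[f"model{model_id}"] = predict_fused(spec, test_features)
        else:
            scores[f"model{model_id}"] = test_features[feats[0]].to_numpy(dtype=float)
    return scores, specs
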