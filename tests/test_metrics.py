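"""Evaluation statistics against brute-force oracles, closed forms and
Monte-Carlo limits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

import oracles
from rsipipe.errors import ConfigurationError
from rsipipe.metrics import (
    average_precision,
    bonferroni_alpha,
    bootstrap_eval,
    brier,
    calibration_bins,
    cochran_i2,
    confusion_at_threshold,
    idi,
    net_benefit,
    nri,
    roc_auc,
    threshold_at_sensitivity,
)

TABLES = oracles.small_score_tables()


@pytest.mark.parametrize("i", range(len(TABLES)))
def test_metrics_match_bruteforce_enumeration(i):
    """Every patient-level metric equals exhaustive enumeration on <=10-row tables."""
    s, p_old, y = TABLES[i]
    assert roc_auc(s, y) == pytest.approx(oracles.auc_pair_counting(s, y), abs=1e-12)
    assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
    assert average_precision(s, y) == pytest.approx(oracles.ap_sweep(s, y), abs=1e-12)
    assert average_precision(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)
    thr, spec = threshold_at_sensitivity(s, y, 0.90)
    o_thr, o_spec = oracles.threshold_spec_enumeration(s, y, 0.90)
    assert (thr, spec) == (o_thr, o_spec)
    assert nri(s, p_old, y) == pytest.approx(oracles.nri_updown_counting(s, p_old, y), abs=1e-12)
    assert idi(s, p_old, y) == pytest.approx(oracles.idi_slopes(s, p_old, y), abs=1e-12)
    assert brier(s, y) == pytest.approx(np.mean((s - y) ** 2), abs=1e-12)
    nb = net_benefit(s, y, [0.2, 0.5, 0.8])
    for _, row in nb.iterrows():
        assert row["net_benefit"] == pytest.approx(
            oracles.net_benefit_counting(s, y, row["threshold"]), abs=1e-12
        )
    assert confusion_at_threshold(s, y, 0.5) == oracles.confusion_counting(s, y, 0.5)


def test_auc_trivials_and_monotone_invariance(rng):
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    s = rng.random(50)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    assert roc_auc(np.exp(3 * s), y) == pytest.approx(roc_auc(s, y), abs=1e-12)
    with pytest.raises(ConfigurationError):
        roc_auc(s, np.zeros(50))


def test_average_precision_limits(rng):
    assert average_precision([0.1, 0.9, 0.8, 0.2], [0, 1, 1, 0]) == 1.0
    # random scores: AP converges to prevalence
    n = 100_000
    y = rng.random(n) < 0.3
    s = rng.random(n)
    assert average_precision(s, y.astype(int)) == pytest.approx(0.3, abs=0.01)


def test_threshold_at_sensitivity_examples(rng):
    scores = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 0.05, 0.1])
    labels = np.array([1, 1, 1, 1, 1, 0, 0])
    thr, spec = threshold_at_sensitivity(scores, labels, target=0.8)
    assert thr == pytest.approx(0.4)
    assert spec == 1.0
    # identical score distributions: specificity -> 1 - target
    n = 100_000
    s = rng.random(n)
    y = rng.integers(0, 2, n)
    _, spec = threshold_at_sensitivity(s, y, 0.90)
    assert spec == pytest.approx(0.10, abs=0.01)
    with pytest.raises(ConfigurationError):
        threshold_at_sensitivity(s, y, target=1.5)


def test_nri_idi_closed_forms():
    y = np.array([1, 1, 0, 0])
    p = np.array([0.7, 0.8, 0.2, 0.3])
    assert nri(p, p, y) == 0.0
    assert idi(p, p, y) == 0.0
    # strict improvement everywhere
    assert nri(np.where(y == 1, p + 0.1, p - 0.1), p, y) == 2.0
    # events-only uniform shift of 0.1
    p_new = np.where(y == 1, p + 0.1, p)
    assert idi(p_new, p, y) == pytest.approx(0.1, abs=1e-12)
    with pytest.raises(ConfigurationError):
        nri(p, p, np.ones(4))


def test_brier_and_calibration(rng):
    assert brier([1.0, 0.0], [1, 0]) == 0.0
    assert brier([0.5, 0.5], [1, 0]) == 0.25
    with pytest.raises(ConfigurationError):
        brier([], [])
    # perfectly calibrated simulation: per-bin observed rate ~= mean prediction
    n = 100_000
    p = rng.random(n)
    y = (rng.random(n) < p).astype(int)
    bins = calibration_bins(p, y, n_bins=10)
    for _, row in bins.iterrows():
        se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["count"])
        assert abs(row["observed_rate"] - row["mean_predicted"]) < 3 * max(se, 1e-4)


def test_net_benefit_reference_curves():
    y = np.array([1, 1, 0, 0, 0])
    perfect = np.array([0.9, 0.95, 0.05, 0.1, 0.02])
    nb = net_benefit(perfect, y, np.linspace(0.2, 0.8, 7))
    below = nb[nb["threshold"] < 0.9]
    assert np.allclose(below["net_benefit"], y.mean())  # FP=0, TP/n = prevalence
    assert np.allclose(nb["treat_none"], 0.0)
    assert 1.0 not in set(net_benefit(perfect, y, [0.5, 1.0])["threshold"])


def test_confusion_threshold_extremes():
    s = np.array([0.2, 0.5, 0.9])
    y = np.array([0, 1, 1])
    low = confusion_at_threshold(s, y, 0.0)
    assert low["tn"] == 0 and low["fn"] == 0 and low["tp"] + low["fp"] == 3
    high = confusion_at_threshold(s, y, 1.1)
    assert high["tp"] == 0 and high["fp"] == 0
    with pytest.raises(ConfigurationError):
        confusion_at_threshold(s, y, np.inf)


def _toy_table(rng, n=60):
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    return pd.DataFrame({
        "cspca_label": y,
        "site_id": np.where(rng.random(n) < 0.5, "A", "B"),
        "score": rng.random(n) + 0.5 * y,
    })


def test_bootstrap_determinism_and_self_nri(rng):
    table = _toy_table(rng)
    fn = lambda df: {"auc": roc_auc(df["score"], df["cspca_label"]),
                     "nri_self": nri(df["score"], df["score"], df["cspca_label"])}
    r1 = bootstrap_eval(table, fn, n_boot=300, seed=11)
    r2 = bootstrap_eval(table, fn, n_boot=300, seed=11)
    assert r1.ci == r2.ci
    assert r1.ci["nri_self"] == (0.0, 0.0)
    assert r1.point["nri_self"] == 0.0
    # p-value floor at 2/n_boot for a strictly positive quantity
    assert r1.p_value("auc") == pytest.approx(2 / 300)
    # site-stratified resampling keeps per-site sizes
    r3 = bootstrap_eval(table, fn, n_boot=50, seed=5, clustering="by_site")
    assert np.isfinite(r3.ci["auc"][0])
    with pytest.raises(ConfigurationError):
        bootstrap_eval(table, fn, n_boot=10, seed=0, clustering="by_patient")


def test_bootstrap_ci_monotone_in_level(rng):
    table = _toy_table(rng)
    fn = lambda df: roc_auc(df["score"], df["cspca_label"])
    wide = bootstrap_eval(table, fn, n_boot=400, seed=3, ci_level=0.99)
    narrow = bootstrap_eval(table, fn, n_boot=400, seed=3, ci_level=0.80)
    assert wide.ci["value"][0] <= narrow.ci["value"][0]
    assert wide.ci["value"][1] >= narrow.ci["value"][1]


def test_bonferroni_threshold():
    raw, rounded = bonferroni_alpha(0.05, 7)
    assert raw == pytest.approx(0.05 / 7)
    assert rounded == 0.007
    assert bonferroni_alpha(0.05, 1)[0] == 0.05
    assert bonferroni_alpha(0.05, 5)[0] == pytest.approx(0.01)
    with pytest.raises(ConfigurationError):
        bonferroni_alpha(0.05, 0)


def test_cochran_i2_hand_values(rng):
    f = cochran_i2([0.6, 0.8], [0.05, 0.05], site_ids=["a", "b"])
    assert f.cochran_q == pytest.approx(8.0)
    assert f.i_squared == pytest.approx(87.5)
    assert cochran_i2([0.7, 0.7, 0.7], [0.1, 0.2, 0.3]).i_squared == 0.0
    for _ in range(20):
        est = rng.random(5)
        se = rng.random(5) * 0.5 + 0.01
        i2 = cochran_i2(est, se).i_squared
        assert 0.0 <= i2 <= 100.0
    with pytest.raises(ConfigurationError):
        cochran_i2([0.5, 0.6], [0.0, 0.1])
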