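"""Independent brute-force oracles for the evaluation statistics.

Everything here is deliberately naive — explicit loops and exhaustive
enumeration over patients and score pairs — so the vectorized library
implementations can be checked against a second, independent route.
"""

from __future__ import annotations

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC by exhaustive event/nonevent pair counting, ties worth 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ap_sweep(scores, labels) -> float:
    """Average precision by an explicit descending-threshold sweep."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for c in sorted(set(s), reverse=True):
        called = s >= c
        tp = int((called & (y == 1)).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def threshold_spec_enumeration(scores, labels, target) -> tuple[float, float]:
    """Largest threshold with sensitivity >= target, by scanning all cuts."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    best = None
    for c in sorted(set(s), reverse=True):
        called = s >= c
        sens = (called & (y == 1)).sum() / y.sum()
        if sens >= target:
            best = c
            break
    assert best is not None
    called = s >= best
    spec = ((~called) & (y == 0)).sum() / (y == 0).sum()
    return float(best), float(spec)


def nri_updown_counting(p_new, p_old, labels) -> float:
    y = np.asarray(labels, dtype=int)
    new = np.asarray(p_new, dtype=float)
    old = np.asarray(p_old, dtype=float)
    up_e = down_e = up_n = down_n = 0
    n_e = int((y == 1).sum())
    n_n = int((y == 0).sum())
    for i in range(len(y)):
        if new[i] > old[i]:
            if y[i] == 1:
                up_e += 1
            else:
                up_n += 1
        elif new[i] < old[i]:
            if y[i] == 1:
                down_e += 1
            else:
                down_n += 1
    return (up_e - down_e) / n_e + (down_n - up_n) / n_n


def idi_slopes(p_new, p_old, labels) -> float:
    y = np.asarray(labels, dtype=int)
    new = np.asarray(p_new, dtype=float)
    old = np.asarray(p_old, dtype=float)

    def slope(p):
        return p[y == 1].mean() - p[y == 0].mean()

    return slope(new) - slope(old)


def net_benefit_counting(probabilities, labels, pt) -> float:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    tp = fp = 0
    for i in range(n):
        if p[i] >= pt:
            if y[i] == 1:
                tp += 1
            else:
                fp += 1
    return tp / n - (fp / n) * pt / (1 - pt)


def confusion_counting(scores, labels, threshold) -> dict[str, int]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    out = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for i in range(len(y)):
        call = s[i] >= threshold
        if call and y[i] == 1:
            out["tp"] += 1
        elif call:
            out["fp"] += 1
        elif y[i] == 1:
            out["fn"] += 1
        else:
            out["tn"] += 1
    return out


def small_score_tables(n_tables: int = 30, max_rows: int = 10, seed: int = 123):
    """Random score/label fixtures of <= 10 rows with both classes present,
    mixing continuous and discrete (tied) scores."""
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        n = int(rng.integers(4, max_rows + 1))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        if rng.random() < 0.5:
            s = np.round(rng.random(n), 1)  # coarse grid -> frequent ties
        else:
            s = rng.random(n)
        p_old = rng.random(n)
        tables.append((s, p_old, y))
    return tables
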