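#!/usr/bin/env python
"""Fit the four-compartment RSI model per patient and tabulate RSIrs_max.

Reads the cohort from scratch/cohort, runs the voxelwise nonnegative
least-squares fit, computes the RSIrs map (C1 normalized by the in-prostate
median T2W signal) and its maximum, and writes results/rsirs_biomarker.csv.
Also reports how well the biomarker separates csPCa-positive from negative
patients at the simulated noise level.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import COHORT_DIR, RESULTS, study_cohort_config

import pandas as pd

from rsipipe.cohort import read_cohort
from rsipipe.metrics import roc_auc
from rsipipe.rsi import RSIFitConfig, compute_rsirs, fit_compartments


def main() -> None:
    studies, manifest = read_cohort(COHORT_DIR)
    cfg = study_cohort_config()
    fit = RSIFitConfig(b_values=cfg.b_values, compartment_adcs=cfg.compartment_adcs)

    rows = []
    for s in studies:
        maps = fit_compartments(s.dwi, fit, mask=s.prostate_mask)
        res = compute_rsirs(maps.c1, s.t2w, s.prostate_mask)
        rows.append({
            "patient_id": s.patient_id,
            "rsirs_max": res.rsirs_max,
            "t2w_median_in_mask": res.t2w_median_in_mask,
            "mean_residual_rms": float(maps.residual_rms[s.prostate_mask > 0].mean()),
        })
    table = pd.DataFrame(rows).merge(manifest, on="patient_id")
    table.to_csv(RESULTS / "rsirs_biomarker.csv", index=False)

    auc = roc_auc(table["rsirs_max"], table["cspca_label"])
    print(f"RSIrs_max computed for {len(table)} patients -> results/rsirs_biomarker.csv")
    print(f"patient-level AUC of RSIrs_max alone: {auc:.3f}")
    print(table.groupby("cspca_label")["rsirs_max"].describe()[["mean", "min", "max"]])


if __name__ == "__main__":
    main()
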