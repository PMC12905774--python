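#!/usr/bin/env python
"""Full leave-one-center-out evaluation of the seven-model roster.

Rotates every center except the always-train smallest one, aggregates the
held-out predictions (each patient scored exactly once), restricts to the
BN-BC subset, and writes the per-model performance table with 10 000-resample
percentile-bootstrap CIs, the four curve tables, the per-site forest tables
with I², and a markdown summary under results/loco/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import COHORT_DIR, RESULTS, study_loco_config

from rsipipe.cohort import read_cohort
from rsipipe.loco import run_loco_evaluation
from rsipipe.pipeline import render_report


def main() -> None:
    studies, manifest = read_cohort(COHORT_DIR)
    lcfg = study_loco_config()
    result = run_loco_evaluation(studies, manifest, lcfg)

    out = RESULTS / "loco"
    out.mkdir(parents=True, exist_ok=True)
    result.prediction_table.to_csv(out / "prediction_table.csv", index=False)
    result.fold_summary.to_csv(out / "fold_summary.csv", index=False)
    artifacts = render_report(result, out)

    report = result.report
    print(f"BN-BC patients evaluated: {report.n_patients}")
    print(f"Bonferroni-adjusted alpha: {report.bonferroni_alpha_rounded}")
    for m in range(1, 8):
        auc, lo, hi = report.lookup(m, "auc")
        p = report.p_values_auc_vs_reference.get(m)
        extra = "" if p is None else f"  p_vs_PI-RADS={p:.4g}"
        print(f"model {m}: AUC {auc:.3f} ({lo:.3f}-{hi:.3f}){extra}")
    for metric, by_model in result.forests.items():
        i2 = {m: f"{f.i_squared:.0f}%" for m, f in sorted(by_model.items())}
        print(f"I^2 by model ({metric}): {i2}")
    print("artifacts:", ", ".join(str(p.relative_to(RESULTS)) for p in artifacts.values()))


if __name__ == "__main__":
    main()
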