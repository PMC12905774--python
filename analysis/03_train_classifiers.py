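#!/usr/bin/env python
"""Train the two 3D dense classifiers on one leave-one-center-out fold.

Holds out the largest center, trains the bpMRI (3-channel) and bpMRI+RSI
(5-channel, scalar-fusion) networks on the remaining centers with the
internal stratified validation split, and writes the training histories to
results/ and the checkpoints to scratch/. The full rotation over every
center is run by 04_loco_evaluate.py; this driver exposes the training
behaviour of a single fold.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import COHORT_DIR, GRID, RESULTS, SCRATCH, SEED, study_loco_config

from rsipipe.cohort import read_cohort
from rsipipe.loco import loco_split, prepare_patient_features, rotatable_sites
from rsipipe.metrics import roc_auc
from rsipipe.nn import DenseNetConfig, predict_proba, save_classifier, train_classifier


def main() -> None:
    studies, manifest = read_cohort(COHORT_DIR)
    lcfg = study_loco_config()
    features = prepare_patient_features(studies, lcfg.fit_config, GRID)

    rot, always = rotatable_sites(manifest, lcfg.always_train)
    holdout = manifest["site_id"].value_counts().idxmax()
    tr_ids, val_ids, te_ids = loco_split(manifest, holdout, seed=SEED,
                                         always_train=tuple(always))
    pool = tr_ids + val_ids
    by_id = manifest.set_index("patient_id")
    labels = by_id.loc[pool, "cspca_label"].to_numpy()
    val_indices = np.arange(len(tr_ids), len(pool))

    print(f"held-out center: {holdout} ({len(te_ids)} patients); "
          f"training pool {len(pool)} (val {len(val_ids)})")

    histories = []
    for name, key, net in (
        ("bpmri", "bpmri", DenseNetConfig.tiny(in_channels=3)),
        ("bpmri_rsi", "bpmri_rsi", DenseNetConfig.tiny(in_channels=5, scalar_fusion=True)),
    ):
        x = np.stack([getattr(features[p], key) for p in pool])
        scalars = (np.array([features[p].rsirs_max for p in pool])
                   if net.scalar_fusion else None)
        trained = train_classifier(x, scalars, labels, net, lcfg.train_config,
                                   val_indices=val_indices)
        save_classifier(trained, SCRATCH / f"classifier_{name}.npz")
        h = trained.history.assign(model=name)
        histories.append(h)

        xt = np.stack([getattr(features[p], key) for p in te_ids])
        st = (np.array([features[p].rsirs_max for p in te_ids])
              if net.scalar_fusion else None)
        probs = predict_proba(trained, xt, st)
        auc = roc_auc(probs, by_id.loc[te_ids, "cspca_label"].to_numpy())
        print(f"{name}: best epoch {trained.best_epoch}, "
              f"final val AUC {h['val_auc'].iloc[-1]:.3f}, held-out AUC {auc:.3f}")

    pd.concat(histories, ignore_index=True).to_csv(
        RESULTS / "training_history.csv", index=False)
    print("histories -> results/training_history.csv; checkpoints -> scratch/")


if __name__ == "__main__":
    main()
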