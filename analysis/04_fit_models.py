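#!/usr/bin/env python
"""Fit and validate the outcome models on the screened synthetic cohort.

Runs the modeling stage end to end with a leakage-free 75/25 stratified
split: the univariate threshold rule on normalized (R-B)/(R^2+B^2), PCA for
class visualization, and the sequential two-stage PLSDA classifier, plus a
flat single-stage PLSDA for comparison. Writes results/metrics.json,
results/model.json and results/pca_scores.csv.
"""
import json
from pathlib import Path

import pandas as pd

from woundspec import models as mdl
from woundspec import pipeline as pl
from woundspec import stats as st

ROOT = Path(__file__).resolve().parents[1]
SPLIT_SEED = 0


def main() -> None:
    stats = pd.read_csv(ROOT / "results" / "channel_stats.csv")
    cfg = pl.RunConfig(split_seed=SPLIT_SEED, n_perm=199, perm_cv=4,
                       perm_seed=SPLIT_SEED, n_components=2)
    results, features, _, pca_scores, model = pl.analyze_channel_stats(
        stats, cfg, log=print
    )

    # flat single-stage PLSDA on the binary outcome, same split, for contrast
    ds = mdl.LabeledDataset.from_frame(features)
    train, val = mdl.stratified_split(ds, mdl.SplitSpec(cfg.train_fraction, SPLIT_SEED))
    flat = mdl.plsda_fit(train.X, train.y2, A=2)
    flat_acc = float((mdl.plsda_predict(flat, val.X)[1] == val.y2).mean())
    results["flat_plsda_validation_accuracy"] = flat_acc

    pl.write_json(ROOT / "results" / "metrics.json", results)
    pl.write_csv(ROOT / "results" / "pca_scores.csv", pca_scores)
    if model is not None:
        model.save(ROOT / "results" / "model.json")

    cm = results["confusion_matrix"]
    print(f"threshold model accuracy: {results['threshold_model']['accuracy']:.3f} "
          f"(cutoff {results['threshold_model']['cutoff']} on normalized "
          f"(R-B)/(R^2+B^2))")
    print(f"PCA explained variance (2 PCs): "
          f"{[round(v, 3) for v in results['pca_explained_variance']]}")
    print(f"two-stage model validation: accuracy {results['accuracy']:.3f}, "
          f"sensitivity {results['sensitivity']:.3f}, "
          f"specificity {results['specificity']:.3f}, "
          f"DOR {results['dor']:.1f} "
          f"(95% CI {results['dor_ci'][0]:.1f}-{results['dor_ci'][1]:.1f}), "
          f"confusion matrix TP={cm['tp']} FN={cm['fn']} FP={cm['fp']} TN={cm['tn']}")
    print(f"flat single-stage PLSDA validation accuracy: {flat_acc:.3f}")
    print("wrote results/metrics.json, results/model.json, results/pca_scores.csv")


if __name__ == "__main__":
    main()
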