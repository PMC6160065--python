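#!/usr/bin/env python
"""Compute the 14 imaging variables per image from the screened cohort.

Fits the cohort normalizer (per-hospital channel means + pooled variable
means) on all QC-passing images and writes results/features.csv plus the
serialized normalizer. The leakage-free train-only normalizer is refit
inside the modeling stage (03/04); the table written here is the
descriptive, full-cohort view used for group comparisons.
"""
from pathlib import Path

import pandas as pd

from woundspec import features as feat
from woundspec import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    stats = pd.read_csv(ROOT / "results" / "channel_stats.csv")
    kept = stats[stats["qc_pass"].astype(bool)].reset_index(drop=True)
    ref = feat.fit_normalizer(
        ((m["hospital"], feat.ChannelMeans(m["r_mean"], m["g_mean"], m["b_mean"]))
         for _, m in kept.iterrows()),
        fit_population=f"all QC-passing images (n={len(kept)})",
    )
    features = pl.features_from_channel_stats(kept, ref)
    pl.write_csv(ROOT / "results" / "features.csv", features)
    ref.to_json(ROOT / "results" / "normalizer.json")

    print(f"extracted {len(feat.MODEL_PREDICTORS)} predictors "
          f"({len(feat.RAW_INDEX_NAMES) + len(feat.NORM_INDEX_NAMES)} imaging "
          f"variables + 3 covariates) for {len(features)} images")
    for hosp, grp in features.groupby("hospital"):
        print(f"  {hosp}: n={len(grp)}, mean normalized R = {grp['r_norm'].mean():.3f}")
    print("hospital normalization brings both cohorts onto a common scale; "
          "wrote results/features.csv and results/normalizer.json")


if __name__ == "__main__":
    main()
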