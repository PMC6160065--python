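#!/usr/bin/env python
"""Permutation overfitting control for the fitted models.

Shuffles outcome labels and refits the identical two-stage recipe to
estimate the probability that a random model matches the observed
cross-validated accuracy (the "probability of insignificance"). Also runs
the same test on a no-signal cohort as a negative control. Writes
results/permutation.json.
"""
from pathlib import Path

import pandas as pd

from woundspec import models as mdl
from woundspec import pipeline as pl
from woundspec import simulate as sim

ROOT = Path(__file__).resolve().parents[1]
SEED = 0
N_PERM = 199


def _dataset_from_stats(stats: pd.DataFrame) -> mdl.LabeledDataset:
    from woundspec import features as feat

    kept = stats[stats["qc_pass"].astype(bool)].reset_index(drop=True)
    ref = feat.fit_normalizer(
        (m["hospital"], feat.ChannelMeans(m["r_mean"], m["g_mean"], m["b_mean"]))
        for _, m in kept.iterrows()
    )
    return mdl.LabeledDataset.from_frame(pl.features_from_channel_stats(kept, ref))


def main() -> None:
    ds = _dataset_from_stats(pd.read_csv(ROOT / "results" / "channel_stats.csv"))
    recipe = mdl.hierarchical_recipe(A=2)
    observed = mdl.permutation_test(
        ds.X, ds.y3, recipe, n_perm=N_PERM, cv=4, seed=SEED,
        score_transform=mdl.collapse_to_binary,
    )
    print(f"fitted cohort: observed CV accuracy {observed.observed:.3f}, "
          f"probability of insignificance {observed.p_insignificance:.4f} "
          f"({N_PERM} permutations)")

    null_stats = pl.channel_stats_from_cohort(
        sim.sample_cohort(sim.null_config(seed=SEED, image_size=(64, 64)))
    )
    null_ds = _dataset_from_stats(null_stats)
    control = mdl.permutation_test(
        null_ds.X, null_ds.y3, recipe, n_perm=N_PERM, cv=4, seed=SEED,
        score_transform=mdl.collapse_to_binary,
    )
    print(f"no-signal control: observed CV accuracy {control.observed:.3f}, "
          f"probability of insignificance {control.p_insignificance:.4f}")

    pl.write_json(ROOT / "results" / "permutation.json", {
        "n_permutations": N_PERM,
        "fitted_cohort": {
            "observed_cv_accuracy": observed.observed,
            "p_insignificance": observed.p_insignificance,
        },
        "null_control": {
            "observed_cv_accuracy": control.observed,
            "p_insignificance": control.p_insignificance,
        },
    })
    print("wrote results/permutation.json")


if __name__ == "__main__":
    main()
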