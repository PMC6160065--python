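"""Shared fixtures: small synthetic cohorts built once per session."""
from __future__ import annotations

import numpy as np
import pytest

from woundspec import features as feat
from woundspec import models as mdl
from woundspec import pipeline as pl
from woundspec import simulate as sim


def dataset_from_config(cfg: sim.CohortConfig):
    """Cohort -> channel stats -> features -> LabeledDataset (QC applied)."""
    stats = pl.channel_stats_from_cohort(sim.sample_cohort(cfg))
    kept = stats[stats["qc_pass"].astype(bool)].reset_index(drop=True)
    ref = feat.fit_normalizer(
        (m["hospital"], feat.ChannelMeans(m["r_mean"], m["g_mean"], m["b_mean"]))
        for _, m in kept.iterrows()
    )
    features = pl.features_from_channel_stats(kept, ref)
    return stats, features, mdl.LabeledDataset.from_frame(features)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-condition cohort (~80 images at 48x48)."""
    cfg = sim.default_config(seed=11, n_patients=8, image_size=(48, 48))
    return dataset_from_config(cfg)


@pytest.fixture(scope="session")
def textured_render():
    """One clean mid-oxygenation render with its ROI."""
    return sim.render_wound_image(0.6, seed=9, noise_sd=0.012)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
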