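"""Spectral-index computation and the two-stage normalization."""
import math
from dataclasses import replace

import numpy as np
import pytest

from woundspec import features as feat
from woundspec import pipeline as pl
from woundspec import simulate as sim
from woundspec.images import ImageRecord

from conftest import dataset_from_config


def _record(**overrides):
    base = dict(image_id="i1", patient_id="p1", wound_id="w1",
                debridement_index=1, hospital="A", wound_area_cm2=120.0,
                days_post_injury=9.0, age=35.0, outcome="healed")
    base.update(overrides)
    return ImageRecord(**base)


class TestRawIndices:
    def test_hand_arithmetic(self):
        out = feat.compute_raw_indices(feat.ChannelMeans(0.6, 0.5, 0.4))
        assert out["r_minus_b"] == pytest.approx(0.2)
        assert out["r_minus_g"] == pytest.approx(0.1)
        assert out["rb_over_g"] == pytest.approx(0.4)
        assert out["rb_over_r2b2"] == pytest.approx(0.2 / 0.52)

    def test_symmetric_channels_zero_composites(self):
        out = feat.compute_raw_indices(feat.ChannelMeans(1.0, 1.0, 1.0))
        for name in ("r_minus_b", "r_minus_g", "rb_over_g", "rb_over_r2b2"):
            assert out[name] == 0.0

    def test_zero_denominators_flag_missing_not_inf(self):
        out = feat.compute_raw_indices(feat.ChannelMeans(0.0, 0.0, 0.0))
        assert math.isnan(out["rb_over_g"])
        assert math.isnan(out["rb_over_r2b2"])
        out = feat.compute_raw_indices(feat.ChannelMeans(0.5, 0.0, 0.3))
        assert math.isnan(out["rb_over_g"])
        assert math.isfinite(out["rb_over_r2b2"])

    def test_rb_over_g_brightness_invariant_rb_over_r2b2_not(self):
        a = feat.compute_raw_indices(feat.ChannelMeans(0.6, 0.5, 0.4))
        b = feat.compute_raw_indices(feat.ChannelMeans(0.3, 0.25, 0.2))
        assert a["rb_over_g"] == pytest.approx(b["rb_over_g"], abs=1e-12)
        assert a["rb_over_r2b2"] != pytest.approx(b["rb_over_r2b2"], rel=0.1)


class TestNormalizer:
    def test_per_hospital_channel_means_are_simple_means(self):
        ref = feat.fit_normalizer(
            [("A", (0.4, 0.5, 0.3)), ("A", (0.6, 0.5, 0.5))]
        )
        assert np.allclose(ref.hospital_channel_means["A"], (0.5, 0.5, 0.4))

    def test_identical_cohort_channel_normalized_to_one(self):
        ref = feat.fit_normalizer([("A", (0.4, 0.3, 0.2))] * 3)
        ch = feat.normalize_channels("A", feat.ChannelMeans(0.4, 0.3, 0.2), ref)
        assert (ch.r, ch.g, ch.b) == pytest.approx((1.0, 1.0, 1.0))
        for name in ("r", "g", "b"):
            assert ref.variable_means[name] == pytest.approx(1.0)

    def test_identical_cohort_degenerate_composites_raise(self):
        # identical images leave every composite at exactly zero after
        # hospital normalization; dividing by its (zero) mean must be a
        # named error, never inf
        ref = feat.fit_normalizer([("A", (0.4, 0.3, 0.2))] * 3)
        raw = feat.compute_raw_indices(
            feat.normalize_channels("A", feat.ChannelMeans(0.4, 0.3, 0.2), ref)
        )
        with pytest.raises(feat.NormalizationError, match="r_minus_b"):
            feat.normalize_features(raw, ref)

    def test_variable_normalization_divides_by_overall_mean(self):
        ref = feat.NormalizationReference(
            hospital_channel_means={"A": (1.0, 1.0, 1.0)},
            variable_means={n: 3.0 for n in feat.RAW_INDEX_NAMES},
        )
        raw = {n: v for n, v in zip(feat.RAW_INDEX_NAMES, (2, 4, 2, 4, 2, 4, 2))}
        fv = feat.normalize_features(raw, ref)
        assert fv.normalized["r_norm"] == pytest.approx(2 / 3)
        assert fv.normalized["g_norm"] == pytest.approx(4 / 3)

    def test_mean_of_normalized_variables_is_one_when_nondegenerate(self):
        rng = np.random.default_rng(7)
        records = [("A", tuple(rng.uniform(0.2, 0.8, 3))) for _ in range(20)]
        ref = feat.fit_normalizer(records)
        vals = {n: [] for n in ("r_norm", "g_norm", "b_norm",
                                "rb_over_g_norm", "rb_over_r2b2_norm")}
        for hosp, ch in records:
            fv = feat.extract_features(hosp, feat.ChannelMeans(*ch), ref)
            for n in vals:
                vals[n].append(fv.normalized[n])
        for n, v in vals.items():
            assert np.mean(v) == pytest.approx(1.0, abs=1e-10), n

    def test_unknown_hospital_raises(self):
        ref = feat.fit_normalizer([("A", (0.4, 0.3, 0.2))] * 2)
        with pytest.raises(feat.UnknownCohortError):
            feat.normalize_channels("B", feat.ChannelMeans(0.4, 0.3, 0.2), ref)

    def test_json_round_trip(self, tmp_path):
        ref = feat.fit_normalizer([("A", (0.4, 0.5, 0.3)), ("B", (0.6, 0.5, 0.5))])
        ref.to_json(tmp_path / "norm.json")
        back = feat.NormalizationReference.from_json(tmp_path / "norm.json")
        assert back.hospital_channel_means == {
            h: tuple(v) for h, v in ref.hospital_channel_means.items()
        }
        assert back.variable_means == pytest.approx(ref.variable_means)


def test_hospital_gain_invariance_of_all_14_variables():
    """A constant camera gain applied to one hospital cancels exactly in the
    hospital normalization, leaving every imaging variable unchanged."""
    none = {"glare": 0.0, "blur": 0.0, "blood": 0.0}
    base = sim.default_config(seed=5, n_patients=6, image_size=(48, 48),
                              artifact_rates=none, noise_sd=0.0)
    gained = replace(
        base,
        hospitals=tuple(
            replace(h, gain=tuple(0.6 * g for g in h.gain))
            if h.name == "EmoryGrady" else h
            for h in base.hospitals
        ),
    )
    cols = list(feat.RAW_INDEX_NAMES) + list(feat.NORM_INDEX_NAMES)
    _, f1, _ = dataset_from_config(base)
    _, f2, _ = dataset_from_config(gained)
    a, b = f1[cols].to_numpy(), f2[cols].to_numpy()
    assert (np.abs(a - b) / np.maximum(1.0, np.abs(a))).max() <= 1e-10


def test_gain_balanced_cohorts_have_matching_normalized_distributions():
    """Two hospitals imaging the same biology with different gains agree in
    hospital-normalized feature distributions within sampling error."""
    cfg = sim.default_config(seed=21, n_patients=24, image_size=(48, 48),
                             artifact_rates={"glare": 0, "blur": 0, "blood": 0})
    _, features, _ = dataset_from_config(cfg)
    for col in ("r_norm", "rb_over_r2b2_norm"):
        groups = features.groupby("hospital")[col]
        means = groups.mean()
        sems = groups.sem()
        gap = abs(means.iloc[0] - means.iloc[1])
        assert gap <= 2.5 * np.hypot(sems.iloc[0], sems.iloc[1]), col


class TestModelInput:
    def test_17_predictors_in_canonical_order(self):
        ref = feat.fit_normalizer([("A", (0.5, 0.45, 0.35)), ("A", (0.6, 0.5, 0.4))])
        fv = feat.extract_features("A", feat.ChannelMeans(0.6, 0.5, 0.4), ref)
        x = feat.assemble_model_input(fv, _record())
        assert x.shape == (17,)
        assert len(feat.MODEL_PREDICTORS) == 17
        assert x[14:].tolist() == [120.0, 9.0, 35.0]
        assert len(fv.as_array()) == 14

    def test_missing_covariate_lists_fields(self):
        ref = feat.fit_normalizer([("A", (0.5, 0.45, 0.35)), ("A", (0.6, 0.5, 0.4))])
        fv = feat.extract_features("A", feat.ChannelMeans(0.6, 0.5, 0.4), ref)
        with pytest.raises(feat.IncompleteRecordError, match="age"):
            feat.assemble_model_input(fv, _record(age=math.nan))

    def test_raw_composites_satisfy_defining_arithmetic(self, small_cohort):
        _, features, _ = small_cohort
        r, g, b = (features[c].to_numpy() for c in ("r", "g", "b"))
        assert np.allclose(features["r_minus_b"], r - b, atol=1e-12)
        assert np.allclose(features["rb_over_g"], (r - b) / g, atol=1e-12)
        assert np.allclose(features["rb_over_r2b2"], (r - b) / (r**2 + b**2), atol=1e-12)
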