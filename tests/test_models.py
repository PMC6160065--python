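"""Threshold rule, PCA, PLSDA, the two-stage classifier, and permutation tests."""
import math

import numpy as np
import pytest

from woundspec import models as mdl


def _random_binary(rng, n):
    y = (rng.uniform(size=n) > 0.5).astype(float)
    if len(set(y)) < 2:  # ensure both classes
        y[0], y[1] = 0.0, 1.0
    return y


class TestThresholdClassify:
    def test_boundary_inclusive_rule(self):
        labels = mdl.threshold_classify([1.20, 1.00, 0.80])
        assert labels.tolist() == ["dehisced", "dehisced", "healed"]

    def test_missing_values_left_unclassified(self):
        labels = mdl.threshold_classify([0.5, math.nan])
        assert labels.tolist() == ["healed", "unclassified"]


class TestStratifiedSplit:
    def _dataset(self, n=100, n_pos=20):
        rng = np.random.default_rng(0)
        y3 = np.array(
            ["dehisced"] * n_pos
            + ["delayed"] * ((n - n_pos) // 2)
            + ["healed"] * (n - n_pos - (n - n_pos) // 2),
            dtype=object,
        )
        return mdl.LabeledDataset(rng.standard_normal((n, 3)), y3, np.arange(n))

    def test_prevalence_preserved(self):
        ds = self._dataset()
        train, val = mdl.stratified_split(ds, mdl.SplitSpec(0.75, seed=3))
        assert (train.y3 == "dehisced").sum() == 15
        assert (val.y3 == "dehisced").sum() == 5

    def test_deterministic_and_partition(self):
        ds = self._dataset()
        a1 = mdl.stratified_split(ds, mdl.SplitSpec(0.75, seed=9))
        a2 = mdl.stratified_split(ds, mdl.SplitSpec(0.75, seed=9))
        assert np.array_equal(a1[0].ids, a2[0].ids)
        combined = np.sort(np.concatenate([a1[0].ids, a1[1].ids]))
        assert np.array_equal(combined, ds.ids)

    def test_singleton_class_raises(self):
        ds = mdl.LabeledDataset(
            np.zeros((3, 2)),
            np.array(["healed", "healed", "dehisced"], dtype=object),
            np.arange(3),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            mdl.stratified_split(ds, mdl.SplitSpec(0.75, 0))


class TestPCA:
    def test_collinear_data_first_component_dominates(self, rng):
        t = rng.standard_normal(50)
        X = np.column_stack([t, 2 * t + 1e-6 * rng.standard_normal(50)])
        _, _, evr = mdl.pca_fit(X, k=2)
        assert evr[0] >= 0.999

    def test_scores_times_loadings_reconstruct(self, rng):
        X = rng.standard_normal((20, 5))
        scores, loadings, _ = mdl.pca_fit(X, k=5)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(scores @ loadings.T, Xs, atol=1e-10)

    def test_column_permutation_permutes_loadings_only(self, rng):
        X = rng.standard_normal((15, 4))
        perm = [2, 0, 3, 1]
        s1, l1, _ = mdl.pca_fit(X, k=2)
        s2, l2, _ = mdl.pca_fit(X[:, perm], k=2)
        # singular vectors are sign-ambiguous; align before comparing
        signs = np.sign((s1 * s2).sum(axis=0))
        assert np.allclose(s2 * signs, s1, atol=1e-8)
        assert np.allclose(l2 * signs, l1[perm], atol=1e-8)

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.column_stack([rng.standard_normal(10), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            _, loadings, _ = mdl.pca_fit(X, k=2)
        assert loadings.shape[0] == 1


class TestPLSDA:
    def test_univariate_equals_ols(self, rng):
        X = rng.standard_normal((12, 1))
        y = _random_binary(rng, 12)
        model = mdl.plsda_fit(X, y, A=1)
        yhat, _ = mdl.plsda_predict(model, X)
        Z = np.column_stack([np.ones(12), (X - X.mean(0)) / X.std(0, ddof=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        assert np.allclose(yhat, Z @ beta, atol=1e-10)

    def test_full_rank_pls_equals_least_squares(self, rng):
        """At A = rank(X) the PLS fit spans the full predictor space, so the
        fitted values coincide with ordinary least squares."""
        worst = 0.0
        for _ in range(100):
            X = rng.standard_normal((10, 3))
            y = _random_binary(rng, 10)
            model = mdl.plsda_fit(X, y, A=3)
            yhat, _ = mdl.plsda_predict(model, X)
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            Z = np.column_stack([np.ones(10), Xs])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            worst = max(worst, float(np.abs(yhat - Z @ beta).max()))
        assert worst <= 1e-8

    def test_separable_clusters_zero_training_error(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (15, 2)), rng.normal(3, 0.3, (15, 2))])
        y = np.array([0.0] * 15 + [1.0] * 15)
        model = mdl.plsda_fit(X, y, A=2, classes=(0, 1))
        _, labels = mdl.plsda_predict(model, X)
        assert ((labels == 1) == (y == 1)).all()

    def test_component_scores_orthogonal(self, rng):
        X = rng.standard_normal((40, 8))
        y = _random_binary(rng, 40)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        _, _, _, T = mdl._nipals_pls1(Xs, y - y.mean(), 4)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8

    def test_regression_vector_matches_deflation_predictions(self, rng):
        X = rng.standard_normal((30, 6))
        y = _random_binary(rng, 30)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        W, P, q, T = mdl._nipals_pls1(Xs, y - y.mean(), 3)
        b = W @ np.linalg.solve(P.T @ W, q)
        assert np.abs(T @ q - Xs @ b).max() <= 1e-10

    def test_predict_on_training_reproduces_fit(self, rng):
        X = rng.standard_normal((25, 5))
        y = _random_binary(rng, 25)
        model = mdl.plsda_fit(X, y, A=2)
        s1, _ = mdl.plsda_predict(model, X)
        s2, _ = mdl.plsda_predict(model, X.copy())
        assert np.allclose(s1, s2, atol=1e-12)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_matches_reference_pls_regression(self, rng, n_components):
        """Cross-check against scikit-learn's PLSRegression (independent
        NIPALS implementation) on the same autoscaled problem."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((30, 6))
        y = _random_binary(rng, 30)
        ours, _ = mdl.plsda_predict(mdl.plsda_fit(X, y, A=n_components), X)
        ref = PLSRegression(n_components=n_components, scale=True).fit(X, y)
        assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-10)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="classes"):
            mdl.plsda_fit(rng.standard_normal((10, 2)), np.zeros(10), A=1)

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.standard_normal((6, 2))
        y = _random_binary(rng, 6)
        with pytest.warns(UserWarning, match="truncated"):
            model = mdl.plsda_fit(X, y, A=9)
        assert model.n_components <= 2

    def test_column_count_mismatch_raises(self, rng):
        model = mdl.plsda_fit(rng.standard_normal((10, 3)), _random_binary(rng, 10), A=1)
        with pytest.raises(ValueError, match="columns"):
            mdl.plsda_predict(model, np.zeros((2, 4)))

    def test_auto_selects_low_components_on_simple_signal(self, rng):
        t = np.repeat([0.0, 1.0], 20)
        X = np.column_stack([t + 0.1 * rng.standard_normal(40),
                             rng.standard_normal(40), rng.standard_normal(40)])
        model = mdl.plsda_fit(X, t, A="auto", cv=5, seed=0)
        assert 1 <= model.n_components <= 2


def _three_class_data(rng, n=90):
    """Healed / delayed / dehisced clusters in a 3-feature space."""
    n3 = n // 3
    X = np.vstack([
        rng.normal([2, 0, 0], 0.4, (n3, 3)),     # healed
        rng.normal([0, 2, 0], 0.4, (n3, 3)),     # delayed
        rng.normal([1, 1, 0], 0.4, (n - 2 * n3, 3)),  # dehisced (between)
    ])
    y3 = np.array(["healed"] * n3 + ["delayed"] * n3
                  + ["dehisced"] * (n - 2 * n3), dtype=object)
    return mdl.LabeledDataset(X, y3, np.arange(n))


class TestHierarchical:
    def test_missing_delayed_class_raises(self, rng):
        ds = _three_class_data(rng)
        keep = ds.y3 != "delayed"
        with pytest.raises(ValueError, match="delayed"):
            mdl.fit_hierarchical(ds.subset(np.flatnonzero(keep)), A=1)

    def test_stage2_trained_on_true_not_delayed_rows(self, rng):
        ds = _three_class_data(rng)
        h = mdl.fit_hierarchical(ds, A=1, route_by="truth")
        # stage-2 preprocessing means reveal its training rows
        not_delayed = ds.X[ds.y3 != "delayed"]
        assert np.allclose(h.stage2.x_mean, not_delayed.mean(0), atol=1e-12)

    def test_final_label_space_is_binary(self, rng):
        ds = _three_class_data(rng)
        h = mdl.fit_hierarchical(ds, A=2)
        labels = mdl.predict_hierarchical(h, rng.standard_normal((50, 3)))
        assert set(labels) <= {"healed", "dehisced"}

    def test_stage1_delayed_routes_to_healed(self, rng):
        ds = _three_class_data(rng)
        h = mdl.fit_hierarchical(ds, A=2)
        _, s1 = mdl.plsda_predict(h.stage1, ds.X)
        final = mdl.predict_hierarchical(h, ds.X)
        assert (final[s1 == "delayed"] == "healed").all()

    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        ds = _three_class_data(rng)
        h = mdl.fit_hierarchical(ds, A=2)
        h.save(tmp_path / "model.json")
        back = mdl.HierarchicalWoundClassifier.load(tmp_path / "model.json")
        Xq = rng.standard_normal((20, 3))
        assert (mdl.predict_hierarchical(back, Xq)
                == mdl.predict_hierarchical(h, Xq)).all()


class TestPermutationTest:
    def test_p_formula_and_bounds(self, rng):
        X = rng.standard_normal((32, 3))
        y = np.array(["healed"] * 22 + ["dehisced"] * 10, dtype=object)
        res = mdl.permutation_test(X, y, mdl.plsda_recipe(A=1), n_perm=19,
                                   cv=4, seed=0)
        expected = (1 + int((res.permuted >= res.observed).sum())) / 20
        assert res.p_insignificance == pytest.approx(expected)
        assert 0 < res.p_insignificance <= 1

    def test_separable_signal_attains_minimum_p(self, rng):
        X = np.vstack([rng.normal(-4, 0.2, (16, 2)), rng.normal(4, 0.2, (16, 2))])
        y = np.array(["healed"] * 16 + ["dehisced"] * 16, dtype=object)
        res = mdl.permutation_test(X, y, mdl.plsda_recipe(A=1), n_perm=39,
                                   cv=4, seed=1)
        assert res.p_insignificance == pytest.approx(1 / 40)

    def test_no_signal_vs_constant_scores_gives_p_one(self):
        X = np.zeros((20, 2))
        y = np.array(["healed"] * 14 + ["dehisced"] * 6, dtype=object)

        def constant_recipe(X_tr, y_tr):
            return lambda Xq: np.array(["healed"] * len(Xq), dtype=object)

        res = mdl.permutation_test(X, y, constant_recipe, n_perm=19, cv=4, seed=0)
        assert res.p_insignificance == 1.0

    def test_too_few_permutations_raise(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array(["healed"] * 5 + ["dehisced"] * 5, dtype=object)
        with pytest.raises(ValueError):
            mdl.permutation_test(X, y, mdl.plsda_recipe(A=1), n_perm=5)


def test_collapse_to_binary_maps_delayed_to_healed():
    out = mdl.collapse_to_binary(["healed", "delayed", "dehisced"])
    assert out.tolist() == ["healed", "healed", "dehisced"]
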