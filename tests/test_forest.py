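import numpy as np
import pytest

from funcforest.forest import (
    FunctionalMetricForest,
    FunctionalRandomForest,
    MultivariateRandomForest,
    PerDoseRandomForest,
    ScalarRandomForest,
    fit_forest,
    forest_weights,
    predict_curve,
    predict_scalar,
    predict_summary_from_curve,
    tree_weights,
)
from funcforest.synthetic import SyntheticConfig, make_benchmark


@pytest.fixture(scope="module")
def small_bench():
    cfg = SyntheticConfig(samples_per_cluster=8, n_doses=25, noise_level=0.05,
                          seed=5)
    return make_benchmark(cfg)


class TestScalarForest:
    def test_memorises_training_data_when_fully_grown(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = ScalarRandomForest(n_trees=1, bootstrap=False, min_node_size=1,
                               max_features=4, random_state=0).fit(X, y)
        assert np.allclose(m.predict(X), y)

    def test_different_seeds_different_bootstraps(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m1 = ScalarRandomForest(n_trees=5, random_state=1).fit(X, y)
        m2 = ScalarRandomForest(n_trees=5, random_state=2).fit(X, y)
        assert not np.array_equal(m1.bootstrap_indices_, m2.bootstrap_indices_)

    def test_same_seed_reproducible(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        p1 = ScalarRandomForest(n_trees=5, random_state=1).fit(X, y).predict(X)
        p2 = ScalarRandomForest(n_trees=5, random_state=1).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_constant_targets_predict_constant(self, rng):
        X = rng.normal(size=(10, 3))
        m = ScalarRandomForest(n_trees=3, random_state=0).fit(X, np.full(10, 4.2))
        assert np.allclose(m.predict(X), 4.2)

    def test_shape_mismatch_errors(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="1-d"):
            ScalarRandomForest(n_trees=2).fit(X, rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="2-dimensional"):
            FunctionalRandomForest(n_trees=2).fit(X, rng.normal(size=10))


class TestWeights:
    def test_single_leaf_tree_uniform_weights(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        m = ScalarRandomForest(n_trees=1, bootstrap=False, min_node_size=100,
                               random_state=0).fit(X, y)
        W = m.forest_weights(X[:3])
        assert np.allclose(W, 1.0 / 8)

    def test_pure_leaf_one_hot(self, rng):
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        m = ScalarRandomForest(n_trees=1, bootstrap=False, min_node_size=1,
                               max_features=3, random_state=0).fit(X, y)
        W = m.forest_weights(X)
        assert np.allclose(W, np.eye(9))

    def test_bootstrap_multiplicity_in_weights(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        m = ScalarRandomForest(n_trees=1, bootstrap=True, min_node_size=100,
                               random_state=3).fit(X, y)
        # single leaf: weight of sample i is its bootstrap multiplicity / n
        counts = np.bincount(m.bootstrap_indices_[0], minlength=6)
        W = m.forest_weights(X[:1])
        assert np.allclose(W[0], counts / counts.sum())

    def test_forest_weights_average_tree_weights_and_sum_to_one(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=7, random_state=2).fit(
            b.features, b.targets, doses=b.doses)
        Xq = b.features[:5]
        per_tree = np.mean([m.tree_weights(t, Xq) for t in range(7)], axis=0)
        W = m.forest_weights(Xq)
        assert np.allclose(W, per_tree)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-9)

    def test_thin_wrappers(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=3, random_state=0).fit(
            b.features, b.targets, doses=b.doses)
        w = forest_weights(m, b.features[0])
        assert w.sum() == pytest.approx(1.0)
        assert tree_weights(m, 0, b.features[0]).sum() == pytest.approx(1.0)


class TestCurvePrediction:
    def test_single_shared_leaf_predicts_mean_curve(self):
        X = np.array([[0.0], [1.0]])
        Y = np.array([[0.0, 1.0], [2.0, 3.0]])
        m = FunctionalRandomForest(n_trees=1, bootstrap=False,
                                   min_node_size=10, random_state=0).fit(X, Y)
        assert np.allclose(m.predict(np.array([[0.5]])), [[1.0, 2.0]])

    def test_pure_leaves_reproduce_training_curves(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 6))
        m = FunctionalRandomForest(n_trees=1, bootstrap=False, min_node_size=1,
                                   max_features=3, random_state=0).fit(X, Y)
        assert np.allclose(m.predict(X), Y)

    def test_curve_prediction_is_dosewise_weighted_mean(self, small_bench):
        """Gaussian-mode leaf prediction equals the per-dose weighted average
        of training responses (the scalar prediction rule applied dose-wise)."""
        b = small_bench
        m = FunctionalRandomForest(n_trees=10, random_state=4).fit(
            b.features, b.targets, doses=b.doses)
        Xq = b.features[:6]
        W = m.forest_weights(Xq)
        assert np.allclose(m.predict(Xq), W @ b.targets)

    def test_distribution_variance_nonnegative_and_consistent(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=5, random_state=1).fit(
            b.features, b.targets, doses=b.doses)
        mu, var = m.predict_distribution(b.features[:4])
        assert np.all(var >= 0)
        assert np.allclose(mu, m.predict(b.features[:4]))

    def test_predict_summary_and_curves(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=20, random_state=3).fit(
            b.features, b.targets, doses=b.doses)
        auc = m.predict_summary(b.features[:3], metric="auc")
        assert auc.shape == (3,)
        assert np.all(auc >= 0)
        curves = m.predict_curves(b.features[:2])
        assert len(curves) == 2 and len(curves[0].values) == b.doses.size

    def test_mode_guards(self, small_bench):
        b = small_bench
        frf = FunctionalRandomForest(n_trees=2, random_state=0).fit(
            b.features, b.targets, doses=b.doses)
        rf = ScalarRandomForest(n_trees=2, random_state=0).fit(
            b.features, b.targets[:, 0])
        with pytest.raises(TypeError, match="predict_curve"):
            predict_scalar(frf, b.features[0])
        with pytest.raises(TypeError, match="predict_scalar"):
            predict_curve(rf, b.features[0])
        assert np.isfinite(predict_scalar(rf, b.features[0]))
        assert predict_curve(frf, b.features[0]).values.shape == (b.doses.size,)
        assert np.isfinite(predict_summary_from_curve(frf, b.features[0], "auc"))


class TestReductionIdentities:
    def test_frf_single_dose_equals_rf(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        rf = ScalarRandomForest(n_trees=10, min_node_size=3,
                                random_state=42).fit(X, y)
        frf = FunctionalRandomForest(n_trees=10, min_node_size=3,
                                     random_state=42,
                                     cost="region_ssd").fit(X, y[:, None])
        assert np.array_equal(rf._feat, frf._feat)
        assert np.array_equal(rf._members, frf._members)
        assert np.allclose(rf.predict(X), frf.predict(X)[:, 0])

    def test_mrf_identity_covariance_equals_region_ssd_frf(self, rng):
        X = rng.normal(size=(25, 4))
        Y = rng.normal(size=(25, 6))
        mrf = MultivariateRandomForest(n_trees=8, min_node_size=4,
                                       random_state=9,
                                       covariance="identity").fit(X, Y)
        frf = FunctionalRandomForest(n_trees=8, min_node_size=4,
                                     random_state=9,
                                     cost="region_ssd").fit(X, Y)
        for attr in ("_feat", "_left", "_right", "_members", "_node_count"):
            assert np.array_equal(getattr(mrf, attr), getattr(frf, attr))
        assert np.allclose(np.nan_to_num(mrf._thr), np.nan_to_num(frf._thr))


class TestVariants:
    def test_mrf_per_tree_covariance_fits_and_predicts(self, small_bench):
        b = small_bench
        m = MultivariateRandomForest(n_trees=4, random_state=1).fit(
            b.features, b.targets, doses=b.doses)
        assert m.predict(b.features[:3]).shape == (3, b.doses.size)

    def test_frfl_scalar_leaves_with_functional_cost(self, small_bench):
        b = small_bench
        m = FunctionalMetricForest(n_trees=5, random_state=2, metric="auc").fit(
            b.features, b.targets, doses=b.doses)
        pred = m.predict(b.features[:4])
        assert pred.shape == (4,)
        # prediction is the forest-weighted mean of per-sample AUCs
        W = m.forest_weights(b.features[:4])
        assert np.allclose(pred, W @ m.leaf_metric_)
        # trees are identical to the FRF grown with the same seed/cost
        frf = FunctionalRandomForest(n_trees=5, random_state=2).fit(
            b.features, b.targets, doses=b.doses)
        assert np.array_equal(m._feat, frf._feat)

    def test_divergence_forest_runs(self, rng):
        X = np.vstack([rng.normal(-1, 0.2, size=(8, 3)),
                       rng.normal(1, 0.2, size=(8, 3))])
        Y = np.vstack([np.zeros((8, 4)), np.ones((8, 4))])
        sd = np.full((16, 4), 0.3)
        m = FunctionalRandomForest(n_trees=4, min_node_size=4, max_features=3,
                                   cost="hellinger", omega_points=64,
                                   random_state=0).fit(X, Y, y_sd=sd)
        pred = m.predict(X)
        assert pred[:8].mean() < 0.3 and pred[8:].mean() > 0.7

    def test_divergence_requires_sds(self, rng):
        with pytest.raises(ValueError, match="y_sd"):
            FunctionalRandomForest(n_trees=2, cost="kl").fit(
                rng.normal(size=(6, 2)), rng.normal(size=(6, 3)))

    def test_fit_forest_config_dispatch(self, small_bench):
        b = small_bench
        m = fit_forest(b.features, b.targets,
                       {"mode": "frf", "n_trees": 3, "random_state": 1,
                        "doses": b.doses})
        assert isinstance(m, FunctionalRandomForest)
        m2 = fit_forest(b.features, b.targets[:, 0],
                        {"mode": "rf", "n_trees": 3, "random_state": 1})
        assert isinstance(m2, ScalarRandomForest)
        with pytest.raises(ValueError, match="unknown mode"):
            fit_forest(b.features, b.targets, {"mode": "nope"})


class TestVariableImportance:
    def test_vim_arithmetic(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=2, random_state=0).fit(
            b.features, b.targets, doses=b.doses)
        m.vim_picked_ = np.array([10, 0, 4])
        m.vim_selected_ = np.array([3, 0, 4])
        vim = m.variable_importance()
        assert vim[0] == pytest.approx(0.3)
        assert vim[1] == 0.0 and m.never_picked_mask_[1]
        assert vim[2] == pytest.approx(1.0)

    def test_single_informative_feature_with_m_one(self, rng):
        X = np.column_stack([np.arange(12, dtype=float), np.ones(12)])
        y = np.arange(12, dtype=float)
        m = ScalarRandomForest(n_trees=20, max_features=1, min_node_size=1,
                               bootstrap=False, random_state=0).fit(X, y)
        vim = m.variable_importance()
        assert vim[0] == pytest.approx(1.0)  # selected whenever picked
        assert vim[1] == 0.0                 # constant feature never selected

    def test_relevant_features_outrank_noise(self, small_bench):
        b = small_bench
        m = FunctionalRandomForest(n_trees=50, random_state=7).fit(
            b.features, b.targets, doses=b.doses)
        vim = m.variable_importance()
        assert vim[b.relevant_mask].mean() > vim[~b.relevant_mask].mean()


class TestEnsembleStability:
    def test_mae_does_not_degrade_much_with_more_trees(self):
        """Held-out MAE averaged over seeds changes little from 50 to 150
        trees (ensemble stability sanity check, scaled-down data)."""
        maes = {50: [], 150: []}
        for seed in range(10):
            cfg = SyntheticConfig(samples_per_cluster=6, n_doses=15,
                                  noise_level=0.05, seed=100 + seed)
            b = make_benchmark(cfg)
            tr = np.arange(0, b.features.shape[0], 2)
            te = np.arange(1, b.features.shape[0], 2)
            for T in (50, 150):
                m = FunctionalRandomForest(n_trees=T, min_node_size=5,
                                           random_state=seed).fit(
                    b.features[tr], b.targets[tr], doses=b.doses)
                maes[T].append(np.abs(m.predict(b.features[te])
                                      - b.targets_clean[te]).mean())
        assert np.mean(maes[150]) <= 1.1 * np.mean(maes[50])
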