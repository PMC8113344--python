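"""Probability-fusion classifier: prior adjustment, posterior product,
argmax labeling, feature pruning, and the scikit-learn estimator."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier

from annualcover.ensemble import (
    CollectionModel,
    CovariateCollection,
    FusedForestClassifier,
    PriorRaster,
    RFSettings,
    adjust_prior,
    classify,
    fit_collection_model,
    fuse_posterior,
    predict_priors,
    prune_features,
)
from annualcover.grid import Composite, GridSpec
from annualcover.samples import SamplePoints


class TestAdjustPrior:
    def test_zero_prior_floors_at_one_sixtieth(self):
        assert adjust_prior(0.0, 0.7, 18) == pytest.approx(0.016667, abs=1e-6)
        assert adjust_prior(0.0, 0.7, 18) == pytest.approx(1.0 / 60.0)

    def test_unit_prior(self):
        assert adjust_prior(1.0, 0.7, 18) == pytest.approx(0.716667, abs=1e-6)

    def test_c_one_is_identity(self):
        for p in (0.0, 0.3, 1.0):
            assert adjust_prior(p, 1.0, 18) == pytest.approx(p)

    def test_out_of_range_prior_errors(self):
        with pytest.raises(ValueError):
            adjust_prior(1.2, 0.7, 18)

    def test_array_input_and_range(self):
        p = np.linspace(0, 1, 11)
        out = adjust_prior(p, 0.7, 18)
        assert (out >= (1 - 0.7) / 18 - 1e-12).all()
        assert (out <= 0.7 + (1 - 0.7) / 18 + 1e-12).all()


def prior_raster(prob_vectors, valid=None, grid=None, class_ids=(1, 2, 3)):
    """1×n raster of given per-pixel probability vectors."""
    n = len(prob_vectors)
    grid = grid or GridSpec(0, 0, 30, 1, n)
    probs = np.array(prob_vectors, float).reshape(1, n, len(class_ids))
    v = np.ones((1, n), bool) if valid is None else np.asarray(valid).reshape(1, n)
    return PriorRaster(probs=probs, class_ids=np.array(class_ids), valid=v, grid=grid)


class TestFusion:
    def test_single_collection_c1_posterior_equals_prior(self):
        p = prior_raster([[0.2, 0.5, 0.3]])
        post = fuse_posterior([p], c=1.0)
        np.testing.assert_allclose(post.values[0, 0], [0.2, 0.5, 0.3])

    def test_four_unanimous_collections_hand_value(self):
        one_hot = [[1.0, 0.0, 0.0]]
        priors = [prior_raster(one_hot) for _ in range(4)]
        post = fuse_posterior(priors, c=0.7, n_classes=18)
        # (0.7 + 0.3/18)^4 = (43/60)^4
        assert post.values[0, 0, 0] == pytest.approx(0.716667**4, abs=1e-6)
        assert post.values[0, 0, 0] == pytest.approx((43 / 60) ** 4)
        assert post.values[0, 0, 0] == pytest.approx(0.263796, abs=1e-6)
        assert post.values[0, 0, 1] == pytest.approx((1 / 60) ** 4, rel=1e-6)
        assert post.values[0, 0, 1] == pytest.approx(7.716e-8, rel=1e-3)

    def test_floor_rescues_three_against_one_zero_vote(self):
        """Three confident votes for class k survive one zero-prior
        collection: the floored product still beats uniform voters."""
        confident = prior_raster([[1.0, 0.0, 0.0]])
        dissent = prior_raster([[0.0, 0.0, 1.0]])
        post = fuse_posterior([confident] * 3 + [dissent], c=0.7, n_classes=18)
        p_k = post.values[0, 0, 0]
        assert p_k == pytest.approx(0.716667**3 * (1 / 60), rel=1e-4)
        assert p_k == pytest.approx(6.134e-3, rel=1e-3)
        uniform = adjust_prior(1 / 3, 0.7, 18) ** 4
        assert p_k > uniform
        # and every entry is strictly positive: no annihilation
        assert (post.values[0, 0] > 0).all()

    def test_missing_collection_skipped_not_floored(self):
        confident = prior_raster([[1.0, 0.0, 0.0]])
        absent = prior_raster([[0.0, 0.0, 0.0]], valid=[False])
        post = fuse_posterior([confident, absent], c=0.7, n_classes=18)
        solo = fuse_posterior([confident], c=0.7, n_classes=18)
        np.testing.assert_allclose(post.values, solo.values)
        assert post.contributing[0, 0] == 1

    def test_strict_floor_mode_penalizes_missing(self):
        confident = prior_raster([[1.0, 0.0, 0.0]])
        absent = prior_raster([[0.0, 0.0, 0.0]], valid=[False])
        post = fuse_posterior([confident, absent], c=0.7, n_classes=18,
                              missing="floor")
        solo = fuse_posterior([confident], c=0.7, n_classes=18)
        np.testing.assert_allclose(post.values, solo.values * (1 / 60))

    def test_all_missing_pixel_is_nodata(self):
        absent = prior_raster([[0.0, 0.0, 0.0]], valid=[False])
        post = fuse_posterior([absent, absent], c=0.7)
        assert np.isnan(post.values[0, 0]).all()
        assert not post.valid[0, 0]

    def test_fusion_order_invariance(self):
        rng = np.random.default_rng(0)
        priors = []
        for _ in range(4):
            p = rng.dirichlet(np.ones(3), size=5)
            priors.append(prior_raster(p, grid=GridSpec(0, 0, 30, 1, 5)))
        a = fuse_posterior(priors, c=0.7).values
        b = fuse_posterior(priors[::-1], c=0.7).values
        np.testing.assert_allclose(a, b)

    def test_class_order_mismatch_errors(self):
        a = prior_raster([[1, 0, 0]], class_ids=(1, 2, 3))
        b = prior_raster([[1, 0, 0]], class_ids=(1, 3, 2))
        with pytest.raises(ValueError):
            fuse_posterior([a, b])


class TestClassify:
    def test_dominant_class_wins(self):
        post = fuse_posterior([prior_raster([[0.1, 0.8, 0.1]])], c=1.0)
        labels = classify(post)
        assert labels.values[0, 0] == 2

    def test_exact_tie_goes_to_lowest_class_id(self):
        post = fuse_posterior([prior_raster([[0.4, 0.4, 0.2]])], c=1.0)
        assert classify(post).values[0, 0] == 1

    def test_scaling_posterior_leaves_argmax_unchanged(self):
        p = prior_raster([[0.2, 0.5, 0.3]])
        post = fuse_posterior([p], c=0.7)
        scaled = fuse_posterior([p], c=0.7)
        scaled.values = scaled.values * 123.4
        assert classify(post).values[0, 0] == classify(scaled).values[0, 0]

    def test_nodata_propagates_to_sentinel(self):
        absent = prior_raster([[0, 0, 0]], valid=[False])
        labels = classify(fuse_posterior([absent], c=0.7))
        assert labels.values[0, 0] == 0


def toy_collection(n=60, n_features=5, separable=True, seed=0):
    """Collection + training where feature 0 alone determines the class."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(0, 0, 30, 1, n)
    y = np.where(np.arange(n) < n // 2, 1, 2)
    layers = {}
    for f in range(n_features):
        if f == 0 and separable:
            values = np.where(y == 1, 0.1, 0.9) + rng.normal(0, 0.01, n)
        else:
            values = rng.uniform(0, 1, n)
        layers[f"feat{f}"] = values.reshape(1, n)
    comp = Composite(layers=layers, season="dry", year=2020,
                     valid_count=np.ones(grid.shape, np.int32), grid=grid)
    coll = CovariateCollection("optical_dry", comp)
    training = SamplePoints.from_arrays(np.zeros(n, int), np.arange(n), y)
    return coll, training, y


class TestCollectionModels:
    def test_separable_training_reaches_perfect_prior_accuracy(self):
        coll, training, y = toy_collection()
        model = fit_collection_model(coll, training, RFSettings(n_estimators=50))
        priors = predict_priors(model, coll)
        pred = priors.class_ids[np.argmax(priors.probs[0], axis=-1)]
        assert (pred == y).all()

    def test_probabilities_sum_to_one(self):
        coll, training, _ = toy_collection()
        model = fit_collection_model(coll, training, RFSettings(n_estimators=50))
        priors = predict_priors(model, coll)
        np.testing.assert_allclose(priors.probs[priors.valid].sum(axis=-1), 1.0)

    def test_deterministic_given_seed(self):
        coll, training, _ = toy_collection()
        a = predict_priors(
            fit_collection_model(coll, training, RFSettings(seed=42)), coll
        )
        b = predict_priors(
            fit_collection_model(coll, training, RFSettings(seed=42)), coll
        )
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_single_class_training_errors(self):
        coll, training, _ = toy_collection()
        mono = training.subset(training.class_ids == 1)
        with pytest.raises(ValueError):
            fit_collection_model(coll, mono)

    def test_nodata_feature_pixel_has_nodata_prior(self):
        coll, training, _ = toy_collection()
        coll.composite.layers["feat1"][0, 0] = np.nan
        train_ok = training.subset(np.arange(len(training)) != 0)
        model = fit_collection_model(coll, train_ok, RFSettings(n_estimators=20))
        priors = predict_priors(model, coll)
        assert not priors.valid[0, 0]
        assert priors.valid[0, 1]

    def test_nonfinite_training_features_error(self):
        coll, training, _ = toy_collection()
        coll.composite.layers["feat0"][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_collection_model(coll, training)

    def test_single_collection_c1_equals_forest_argmax(self):
        """With one collection and c=1 the fused pipeline reduces to the
        forest's own prediction, pixel for pixel."""
        coll, training, _ = toy_collection(seed=5)
        model = fit_collection_model(coll, training, RFSettings(n_estimators=50))
        priors = predict_priors(model, coll)
        labels = classify(fuse_posterior([priors], c=1.0))
        direct = model.forest.predict(
            np.column_stack([coll.composite.layers[f][0] for f in coll.feature_names])
        )
        np.testing.assert_array_equal(labels.values[0], direct)


class TestPruneFeatures:
    def test_full_retention_drops_nothing(self):
        coll, training, _ = toy_collection()
        pruned = prune_features(coll, training, retention=1.0)
        assert pruned.feature_names == coll.feature_names

    def test_informative_feature_survives_aggressive_pruning(self):
        coll, training, _ = toy_collection(n_features=10)
        pruned = prune_features(coll, training, retention=0.5,
                                settings=RFSettings(n_estimators=50))
        assert "feat0" in pruned.feature_names

    def test_at_least_one_feature_always_kept(self):
        coll, training, _ = toy_collection(n_features=3)
        pruned = prune_features(coll, training, retention=0.001)
        assert len(pruned.feature_names) >= 1

    def test_bad_retention_errors(self):
        coll, training, _ = toy_collection()
        with pytest.raises(ValueError):
            prune_features(coll, training, retention=0.0)


class TestFusedForestClassifier:
    def make_xy(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.where(np.arange(n) < n // 2, 1, 2)
        block_a = np.column_stack(
            [np.where(y == 1, 0.1, 0.9) + rng.normal(0, 0.02, n),
             rng.uniform(0, 1, n)]
        )
        block_b = np.column_stack(
            [np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.5, n),
             rng.uniform(0, 1, n)]
        )
        return np.hstack([block_a, block_b]), y

    SLICES = {"optical": (0, 2), "sar": (2, 4)}

    def test_sklearn_clone_and_params_roundtrip(self):
        est = FusedForestClassifier(n_estimators=10, c=0.5,
                                    collection_slices=self.SLICES)
        cloned = clone(est)
        assert cloned.get_params()["c"] == 0.5
        cloned.set_params(c=0.9)
        assert cloned.c == 0.9 and est.c == 0.5

    def test_fit_predict_recovers_labels(self):
        X, y = self.make_xy()
        est = FusedForestClassifier(
            n_estimators=30, collection_slices=self.SLICES, random_state=0
        )
        pred = est.fit(X, y).predict(X)
        assert (pred == y).mean() >= 0.99
        assert hasattr(est, "classes_") and hasattr(est, "forests_")

    def test_predict_proba_rows_sum_to_one(self):
        X, y = self.make_xy()
        est = FusedForestClassifier(
            n_estimators=30, collection_slices=self.SLICES, random_state=0
        ).fit(X, y)
        np.testing.assert_allclose(est.predict_proba(X).sum(axis=1), 1.0)

    def test_nan_block_skips_that_collection(self):
        X, y = self.make_xy()
        est = FusedForestClassifier(
            n_estimators=30, collection_slices=self.SLICES, random_state=0
        ).fit(X, y)
        X_missing = X.copy()
        X_missing[:, 2:] = np.nan  # SAR block gone
        pred = est.predict(X_missing)
        assert (pred == y).mean() >= 0.99

    def test_single_block_c1_equals_plain_forest(self):
        X, y = self.make_xy()
        est = FusedForestClassifier(n_estimators=40, c=1.0, random_state=7).fit(X, y)
        rf = RandomForestClassifier(
            n_estimators=40, max_features=min(8, X.shape[1]),
            random_state=7, n_jobs=1,
        ).fit(X, y)
        np.testing.assert_array_equal(est.predict(X), rf.predict(X))

    def test_end_to_end_recovery_meets_target(self, end_to_end):
        """Four-collection synthetic recovery: held-out OA >= 95% with
        5-SD class separation and 30% cloud."""
        assert end_to_end.oa >= 95.0
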