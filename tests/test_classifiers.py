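"""Weighted LDA (closed form) and weighted one-against-one SVM."""

import numpy as np
import pytest

from beatselect.classifiers import (
    WSVMSpec, WeightedLDA, WeightedSVM, fit_wlda, fit_wsvm, predict_wlda,
    resolve_class_weights,
)


def _random_problem(rng, n=50, d=5, k=3):
    X = rng.normal(0, 1, (n, d))
    y = rng.integers(0, k, n)
    while len(np.unique(y)) < k:  # ensure every class occupied
        y = rng.integers(0, k, n)
    return X, y


def _brute_force_sigma(X, y, weights, classes):
    """Direct double-sum of the weighted pooled scatter."""
    d = X.shape[1]
    num = np.zeros((d, d))
    den = 0.0
    for cls in classes:
        Xk = X[y == cls]
        mu = Xk.mean(axis=0)
        for x in Xk:
            dev = (x - mu)[:, None]
            num += weights[cls] * dev @ dev.T
        den += weights[cls] * len(Xk)
    return num / den


class TestWeightedLDA:
    def test_equal_weights_reduce_to_plain_lda(self, rng):
        X, y = _random_problem(rng)
        model = fit_wlda(X, y, class_weights="uniform")
        # unweighted closed form: pooled scatter / N
        sigma = sum(
            ((X[y == c] - X[y == c].mean(axis=0)).T
             @ (X[y == c] - X[y == c].mean(axis=0)))
            for c in model.classes_
        ) / len(X)
        assert np.allclose(model.covariance_, sigma, atol=1e-12)

    def test_one_dimensional_degenerate_classes(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_wlda(X, y, class_weights={0: 1.0, 1: 3.0})
        assert np.allclose(model.means_.ravel(), [0.0, 2.0])
        # zero within-class scatter: covariance is pure ridge
        assert 0 < model.covariance_[0, 0] < 1e-6

    def test_sigma_matches_brute_force(self, rng):
        X, y = _random_problem(rng)
        weights = {0: 1.0, 1: 2.5, 2: 7.0}
        model = fit_wlda(X, y, class_weights=weights)
        expected = _brute_force_sigma(X, y, weights, model.classes_)
        assert np.max(np.abs(model.covariance_ - expected)) < 1e-10

    def test_discriminant_matches_formula(self, rng):
        X, y = _random_problem(rng, n=60, d=2)
        model = fit_wlda(X, y)
        sigma_inv = np.linalg.inv(model.covariance_)
        x = rng.normal(0, 1, 2)
        scores = model.decision_function(x[None, :])[0]
        for k, mu in enumerate(model.means_):
            expected = -0.5 * mu @ sigma_inv @ mu + mu @ sigma_inv @ x
            assert scores[k] == pytest.approx(expected, abs=1e-10)

    def test_predicts_class_of_its_mean(self, rng):
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([m + rng.normal(0, 0.1, (30, 2)) for m in means])
        y = np.repeat([0, 1, 2], 30)
        model = fit_wlda(X, y)
        assert list(predict_wlda(model, model.means_)) == [0, 1, 2]

    def test_identity_covariance_is_nearest_mean(self, rng):
        # two well-separated spherical classes: decision = nearest mean
        X = np.vstack([rng.normal(-2, 1, (200, 3)), rng.normal(2, 1, (200, 3))])
        y = np.repeat([0, 1], 200)
        model = fit_wlda(X, y, class_weights="uniform")
        probe = rng.normal(0, 3, (50, 3))
        nearest = np.argmin(
            [np.sum((probe - m) ** 2, axis=1) for m in model.means_], axis=0
        )
        # Mahalanobis reduces to Euclidean when Sigma ~ isotropic
        model.covariance_ = np.eye(3)
        model._sigma_inv_means = model.means_.copy()
        assert np.array_equal(model.predict(probe), model.classes_[nearest])

    def test_translation_invariance(self, rng):
        X, y = _random_problem(rng)
        shift = rng.normal(0, 5, X.shape[1])
        a = fit_wlda(X, y).predict(X)
        b = fit_wlda(X + shift, y).predict(X + shift)
        assert np.array_equal(a, b)

    def test_weight_for_absent_class_is_an_error(self, rng):
        X, y = _random_problem(rng, k=2)
        with pytest.raises(ValueError, match="absent"):
            fit_wlda(X, y, class_weights={0: 1.0, 1: 1.0, 9: 4.0})

    def test_json_round_trip(self, rng, tmp_path):
        X, y = _random_problem(rng)
        model = fit_wlda(X, y)
        model.to_json(tmp_path / "m.json")
        back = WeightedLDA.from_json(tmp_path / "m.json")
        probe = rng.normal(0, 1, (20, X.shape[1]))
        assert np.array_equal(
            model.predict(probe).astype(str), back.predict(probe)
        )


class TestInversePriorWeights:
    def test_normalized_to_sum_k(self):
        y = np.array(["N"] * 90 + ["V"] * 10)
        w = resolve_class_weights(y, ["N", "V"], "inverse-prior")
        assert sum(w.values()) == pytest.approx(2.0)
        assert w["V"] / w["N"] == pytest.approx(9.0)


class TestWeightedSVM:
    def test_separable_data_degree_one(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))])
        y = np.repeat([0, 1], 40)
        model = fit_wsvm(X, y, WSVMSpec(kernel_degree=1, C=1.0))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_one_against_one_builds_all_pairs(self, rng):
        X = rng.normal(0, 1, (60, 3))
        y = np.repeat([0, 1, 2, 3], 15)
        model = fit_wsvm(X, y)
        assert len(model.models_) == 6  # K(K-1)/2 for K=4

    def test_weighting_equivalent_to_resampling(self, rng):
        # duplicating each minority sample m times ~ weighting c_minority=m
        m = 4
        X_maj = rng.normal(0, 1.0, (80, 2))
        X_min = rng.normal(1.5, 1.0, (12, 2))
        X = np.vstack([X_maj, X_min])
        y = np.array([0] * 80 + [1] * 12)
        X_dup = np.vstack([X_maj, np.repeat(X_min, m, axis=0)])
        y_dup = np.array([0] * 80 + [1] * 12 * m)
        spec_w = WSVMSpec(kernel_degree=2, C=1.0, class_weights={0: 1.0, 1: float(m)})
        spec_d = WSVMSpec(kernel_degree=2, C=1.0, class_weights={0: 1.0, 1: 1.0})
        weighted = fit_wsvm(X, y, spec_w)
        duplicated = fit_wsvm(X_dup, y_dup, spec_d)
        gx, gy = np.meshgrid(np.linspace(-3, 4, 15), np.linspace(-3, 4, 15))
        grid = np.c_[gx.ravel(), gy.ravel()]
        agreement = np.mean(weighted.predict(grid) == duplicated.predict(grid))
        assert agreement > 0.97

    def test_increasing_minority_weight_helps_minority_recall(self, rng):
        X = np.vstack([rng.normal(0, 1.2, (150, 2)), rng.normal(1.4, 1.2, (15, 2))])
        y = np.array([0] * 150 + [1] * 15)
        recalls = []
        for w in (1.0, 4.0, 16.0):
            spec = WSVMSpec(kernel_degree=2, C=1.0, class_weights={0: 1.0, 1: w})
            pred = fit_wsvm(X, y, spec).predict(X)
            recalls.append(np.mean(pred[y == 1] == 1))
        assert recalls[2] >= recalls[0]  # monotone up to solver noise

    def test_spec_grid_bounds(self):
        with pytest.raises(ValueError):
            WSVMSpec(kernel_degree=5)
        with pytest.raises(ValueError):
            WSVMSpec(C=1e6)

    def test_nonfinite_features_rejected(self, rng):
        X = rng.normal(0, 1, (20, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_wsvm(X, np.repeat([0, 1], 10))
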