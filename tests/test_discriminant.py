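"""Diagonal Gaussian discriminant: closed-form checks and CV protocol."""

import numpy as np
import pytest
from scipy.optimize import brentq
from sklearn.base import clone

from clonorigin import (
    DiagonalDiscriminant,
    ValidationError,
    cross_validate_origin,
    resubstitution_report,
)


def two_gaussian_classes(rng, mu=(1.0, -1.0), sd=1.0, n=200):
    X = np.concatenate([rng.normal(mu[0], sd, n), rng.normal(mu[1], sd, n)])
    y = np.array(["pos"] * n + ["neg"] * n)
    return X[:, None], y


class TestFit:
    def test_class_below_two_samples_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValidationError):
            DiagonalDiscriminant().fit(X, np.array(["a", "a", "b"]))

    def test_duplicating_samples_leaves_model_unchanged(self):
        rng = np.random.default_rng(0)
        X, y = two_gaussian_classes(rng, n=30)
        one = DiagonalDiscriminant().fit(X, y)
        two = DiagonalDiscriminant().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(one.means_, two.means_)
        np.testing.assert_allclose(one.log_priors_, two.log_priors_)
        # pooled variance uses n - C dof, so it shrinks slightly but stays close
        np.testing.assert_allclose(one.variances_, two.variances_, rtol=0.05)

    def test_variance_floor_keeps_constant_feature_finite(self):
        X = np.column_stack([np.repeat([0.0, 1.0], 5), np.full(10, 3.0)])
        y = np.repeat(["a", "b"], 5)
        model = DiagonalDiscriminant(var_floor=1e-6).fit(X, y)
        assert model.variances_[1] == 1e-6
        assert np.isfinite(model.decision_function(X)).all()

    def test_full_covariance_requires_fewer_features_than_samples(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 12))
        y = np.repeat(["a", "b"], 5)
        with pytest.raises(ValidationError):
            DiagonalDiscriminant(covariance="full").fit(X, y)
        model = DiagonalDiscriminant(covariance="full").fit(X[:, :3], y)
        assert model.predict(X[:, :3]).shape == (10,)


class TestClassify:
    def test_class_mean_maps_to_its_class(self):
        rng = np.random.default_rng(2)
        X, y = two_gaussian_classes(rng)
        model = DiagonalDiscriminant(priors="uniform").fit(X, y)
        assert model.predict(model.means_).tolist() == list(model.classes_)

    def test_midpoint_tie_is_flagged(self):
        X = np.array([[1.0], [1.2], [-1.0], [-1.2]])
        y = np.array(["a", "a", "b", "b"])
        model = DiagonalDiscriminant(priors="uniform").fit(X, y)
        labels, _, ties = model.predict_verbose(np.array([[0.0]]))
        assert ties[0]
        assert labels[0] == "a"  # tie resolves to earlier class label

    def test_closed_form_lda_boundary(self):
        """Two classes, one feature: boundary matches the textbook threshold.

        x* = (mu1 + mu2)/2 - s^2 (log pi1 - log pi2) / (mu1 - mu2)
        """
        rng = np.random.default_rng(3)
        X, y = two_gaussian_classes(rng, mu=(1.3, -0.7), sd=0.9, n=150)
        model = DiagonalDiscriminant().fit(X, y)
        mu_neg, mu_pos = model.means_[:, 0]  # classes sorted: neg, pos
        s2 = model.variances_[0]
        lp_neg, lp_pos = model.log_priors_
        expected = (mu_neg + mu_pos) / 2 - s2 * (lp_neg - lp_pos) / (mu_neg - mu_pos)

        def score_gap(x):
            s = model.decision_function(np.array([[x]]))[0]
            return s[0] - s[1]

        numeric = brentq(score_gap, -10, 10, xtol=1e-12)
        assert abs(numeric - expected) < 1e-9

    def test_equal_priors_boundary_at_midpoint(self):
        rng = np.random.default_rng(4)
        X, y = two_gaussian_classes(rng, mu=(1.0, -1.0), n=100)
        model = DiagonalDiscriminant(priors="uniform").fit(X, y)
        mid = model.means_[:, 0].mean()
        gap = np.diff(model.decision_function(np.array([[mid]])))[0]
        assert abs(gap) < 1e-9

    def test_scores_shift_invariant_in_log_priors(self):
        rng = np.random.default_rng(5)
        X, y = two_gaussian_classes(rng, n=50)
        model = DiagonalDiscriminant().fit(X, y)
        base = model.decision_function(X)
        model.log_priors_ = model.log_priors_ + 3.7
        shifted = model.decision_function(X)
        np.testing.assert_allclose(shifted - base, 3.7)
        assert (np.argmax(base, 1) == np.argmax(shifted, 1)).all()

    def test_accuracy_invariant_to_feature_and_sample_permutation(self):
        rng = np.random.default_rng(6)
        n = 60
        X = np.column_stack(
            [np.concatenate([rng.normal(0.8, 0.3, n), rng.normal(-0.8, 0.3, n)]),
             rng.normal(size=2 * n)]
        )
        y = np.repeat(["a", "b"], n)
        base = DiagonalDiscriminant().fit(X, y).predict(X)
        perm_f = DiagonalDiscriminant().fit(X[:, ::-1], y).predict(X[:, ::-1])
        order = rng.permutation(2 * n)
        perm_s = DiagonalDiscriminant().fit(X[order], y[order]).predict(X[order])
        assert (base == perm_f).all()
        assert (base == y).mean() == (perm_s == y[order]).mean()

    def test_sklearn_contract(self):
        model = DiagonalDiscriminant(priors="uniform", var_floor=1e-5)
        assert clone(model).get_params() == model.get_params()


class TestCrossValidation:
    def test_separable_classes_are_perfect(self):
        rng = np.random.default_rng(7)
        n = 25
        X = np.column_stack(
            [np.concatenate([rng.normal(2, 0.1, n), rng.normal(-2, 0.1, n)]),
             rng.normal(size=2 * n)]
        )
        y = np.repeat(["a", "b"], n)
        report = cross_validate_origin(X, y, alpha=1e-6, n_splits=5, seed=0)
        assert all(v == 1.0 for v in report.per_class_accuracy.values())
        assert report.confusion.sum(axis=1).tolist() == [n, n]

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(8)
        n, k = 120, 150
        X = rng.normal(size=(n, k))
        y = rng.permutation(np.repeat(["a", "b", "c"], n // 3))
        report = cross_validate_origin(X, y, alpha=0.2, n_splits=5, seed=1,
                                       method="anova")
        assert 0.1 < report.overall_accuracy < 0.6  # chance is 1/3

    def test_no_feature_survives_raises(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 10))
        y = np.repeat(["a", "b"], 20)
        with pytest.raises(ValidationError, match="no signature region"):
            cross_validate_origin(X, y, alpha=1e-300, n_splits=4, seed=0)

    def test_small_class_rejected(self):
        X = np.zeros((7, 2))
        y = np.array(["a"] * 4 + ["b"] * 3)
        with pytest.raises(ValidationError):
            cross_validate_origin(X, y, n_splits=4)

    def test_resubstitution_labelled_and_at_least_as_good(self):
        rng = np.random.default_rng(10)
        n = 30
        X = np.column_stack(
            [np.concatenate([rng.normal(1, 0.5, n), rng.normal(-1, 0.5, n)]),
             rng.normal(size=2 * n)]
        )
        y = np.repeat(["a", "b"], n)
        resub = resubstitution_report(X, y, alpha=1e-3)
        cv = cross_validate_origin(X, y, alpha=1e-3, n_splits=5, seed=2)
        assert resub.protocol == "resubstitution"
        assert "CV" in cv.protocol
        assert resub.overall_accuracy >= cv.overall_accuracy - 0.1
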