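"""Per-region association screening: oracles, calibration, selection."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from clonorigin import CnvSignatureSelector, ValidationError, select_signatures
from clonorigin.signatures import logistic_lrt_scan, score_region_association


def two_class_data(rng, n_per_class=40, effect=0.9, sd=0.1):
    values = np.concatenate(
        [rng.normal(effect, sd, n_per_class), rng.normal(-effect, sd, n_per_class)]
    )
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return values[:, None], labels


class TestLogisticLrtScan:
    def test_constant_region_p_is_one(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50).astype(float)
        y[0] = 1 - y[0] if y.mean() in (0, 1) else y[0]
        X = np.column_stack([np.full(50, 0.3), rng.normal(size=50)])
        p, slopes, flags = logistic_lrt_scan(X, y)
        assert p[0] == 1.0 and flags[0] == "degenerate" and slopes[0] == 0.0

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValidationError):
            logistic_lrt_scan(np.zeros((10, 1)), np.ones(10))

    def test_strong_effect_separated_and_tiny_p(self):
        rng = np.random.default_rng(1)
        X, labels = two_class_data(rng)
        p, slopes, flags = logistic_lrt_scan(X, (labels == "a").astype(float))
        assert p[0] < 1e-12
        assert flags[0] == "separation"
        assert np.isfinite(slopes[0])

    def test_agrees_with_statsmodels_glm(self):
        """Independent per-region oracle: statsmodels binomial GLM LRT."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n, k = 80, 15
        X = rng.normal(size=(n, k))
        # mild effects only, to keep every fit far from separation
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 3]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logits))).astype(float)
        p_fast, slopes, _ = logistic_lrt_scan(X, y)
        for j in range(k):
            exog = sm.add_constant(X[:, j])
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((n, 1)),
                          family=sm.families.Binomial()).fit()
            lrt = 2 * (fit.llf - null.llf)
            p_ref = stats.chi2.sf(max(lrt, 0.0), df=1)
            assert p_fast[j] == pytest.approx(p_ref, rel=1e-5, abs=1e-12)
            assert slopes[j] == pytest.approx(fit.params[1], rel=1e-4, abs=1e-6)

    def test_agrees_with_permutation_oracle(self):
        """The worked strong-effect example also clears a permutation test."""
        rng = np.random.default_rng(2)
        X, labels = two_class_data(rng, effect=0.9, sd=0.1)
        p, _, _ = logistic_lrt_scan(X, (labels == "a").astype(float))
        assert p[0] < 1e-12
        observed = abs(X[labels == "a", 0].mean() - X[labels == "b", 0].mean())
        count = 0
        n_perm = 2000
        y = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(y)
            diff = abs(X[y == "a", 0].mean() - X[y == "b", 0].mean())
            count += diff >= observed
        assert (count + 1) / (n_perm + 1) < 1e-3

    def test_null_pvalues_uniform(self):
        """Shuffled labels give approximately uniform p-values (KS check)."""
        rng = np.random.default_rng(3)
        n, k = 120, 4000
        X = rng.normal(size=(n, k))
        y = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        p, _, _ = logistic_lrt_scan(X, y)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestScoreRegionAssociation:
    def test_min_over_one_vs_rest_classes(self):
        rng = np.random.default_rng(4)
        n = 30
        values = np.concatenate(
            [rng.normal(0.8, 0.1, n), rng.normal(0, 0.1, n), rng.normal(0, 0.1, n)]
        )[:, None]
        labels = np.repeat(["a", "b", "c"], n)
        min_p, class_p, effects, _ = score_region_association(values, labels)
        assert min_p[0] == min(class_p[c][0] for c in "abc")
        assert min_p[0] < 1e-12
        assert effects["a"][0] > 0  # class a sits at elevated values

    def test_requires_two_classes_of_two(self):
        with pytest.raises(ValidationError):
            score_region_association(np.zeros((4, 1)), np.array(["a"] * 4))
        with pytest.raises(ValidationError):
            score_region_association(
                np.zeros((4, 1)), np.array(["a", "a", "a", "b"])
            )

    def test_anova_scorer_ranks_signal_first(self):
        rng = np.random.default_rng(6)
        n = 30
        signal = np.concatenate([rng.normal(0.8, 0.1, n), rng.normal(0, 0.1, 2 * n)])
        noise = rng.normal(0, 0.1, 3 * n)
        X = np.column_stack([signal, noise, np.zeros(3 * n)])
        labels = np.repeat(["a", "b", "c"], n)
        p, *_ , flags = score_region_association(X, labels, method="anova")
        assert p[0] < 1e-12 < p[1]
        assert p[2] == 1.0 and flags[2] == "degenerate"


class TestSelector:
    def test_alpha_one_selects_all_nondegenerate(self, cohort_with_matrix):
        *_, matrix = cohort_with_matrix
        sig = select_signatures(matrix, alpha=1.0)
        nondegenerate = int((np.ptp(matrix.feature_matrix(), axis=0) > 0).sum())
        assert len(sig) == nondegenerate

    def test_alpha_zero_selects_none(self, cohort_with_matrix):
        *_, matrix = cohort_with_matrix
        assert len(select_signatures(matrix, alpha=0.0)) == 0

    def test_planted_regions_recovered_without_misses(self, cohort_with_matrix):
        cohort, truth, matrix = cohort_with_matrix
        sig = select_signatures(matrix, alpha=1e-12)
        selected = set(sig.selected.tolist())
        planted = [iv for cls in truth.planted for iv, _ in truth.planted[cls]]
        inside_planted = {
            i
            for i, region in enumerate(matrix.region_set)
            if any(region.overlaps(iv) for iv in planted)
        }
        assert inside_planted <= selected  # zero misses
        # false positives among null regions: expected count n*alpha ~ 1e-9
        assert not (selected - inside_planted)

    def test_sklearn_contract(self):
        rng = np.random.default_rng(8)
        X, labels = two_class_data(rng)
        X = np.column_stack([X[:, 0], rng.normal(size=len(labels))])
        selector = CnvSignatureSelector(alpha=1e-6)
        cloned = clone(selector)
        assert cloned.get_params() == selector.get_params()
        transformed = selector.fit(X, labels).transform(X)
        assert transformed.shape == (len(labels), 1)
        assert selector.get_support().tolist() == [True, False]
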