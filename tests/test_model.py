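"""Unit tests for the binomial reverse-regression core."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from pleioscan import (
    DegenerateDesignError,
    GenotypeBinomialModel,
    GenotypeCounts,
    MonomorphicError,
    PhenotypeVectorSet,
    binomial_loglik,
    fit_full,
    fit_null,
    lrt_test,
)
from pleioscan.model import _lrt_arrays

from oracles import grid_search_null_beta0, naive_binomial_loglik


class TestLoglik:
    def test_symmetric_heterozygote(self):
        # beta=0 so p=1/2: P(N=1) = C(2,1)/4 = 1/2
        assert binomial_loglik(0.0, [0.0], [[0.0]], [1]) == pytest.approx(
            -math.log(2), abs=1e-12
        )

    def test_closed_form_p075(self):
        # logit(0.75) = log 3; P(N=2) = 0.75^2
        assert binomial_loglik(math.log(3), [0.0], [[0.0]], [2]) == pytest.approx(
            2 * math.log(0.75), abs=1e-12
        )

    def test_matches_term_by_term_summation(self, rng):
        x = rng.normal(size=(10, 1))
        counts = rng.integers(0, 3, size=10)
        got = binomial_loglik(0.0, [1.0], x, counts)
        want = naive_binomial_loglik(0.0, [1.0], x, counts)
        assert got == pytest.approx(want, abs=1e-10)

    def test_extreme_linear_predictor_is_finite(self):
        assert np.isfinite(binomial_loglik(0.0, [700.0], [[1.0], [-1.0], [0.5]], [2, 0, 1]))

    def test_dimension_mismatch_and_nonfinite_errors(self):
        with pytest.raises(ValueError):
            binomial_loglik(0.0, [1.0, 2.0], [[0.0]], [1])
        with pytest.raises(ValueError):
            binomial_loglik(np.nan, [1.0], [[0.0]], [1])


class TestNullFit:
    def test_balanced_counts_give_zero_intercept(self):
        res = fit_null([0, 1, 2, 1])
        assert res.beta0 == pytest.approx(0.0, abs=1e-12)
        assert res.converged

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            fit_null([0, 0, 0])
        with pytest.raises(MonomorphicError):
            fit_null([2, 2])

    def test_matches_grid_search(self):
        counts = [0, 1, 1, 0, 2, 0, 1, 1, 0, 0]
        res = fit_null(counts)
        assert res.beta0 == pytest.approx(
            grid_search_null_beta0(counts), abs=1e-3
        )

    def test_casewise_deletion_of_missing(self):
        geno = GenotypeCounts(np.array([0.0, 1.0, np.nan, 2.0, 1.0]))
        res = fit_null(geno)
        assert res.n_used == 4
        assert res.beta0 == pytest.approx(0.0, abs=1e-12)


class TestFullFit:
    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_full(np.zeros((6, 1)), [0, 1, 2, 1, 0, 1])

    def test_complete_separation_flagged(self):
        res = fit_full(np.array([[-1.0], [1.0]]), [0, 2])
        assert not res.converged

    def test_recovers_simulated_effect(self, small_association_data):
        x, counts = small_association_data
        res = fit_full(x, counts)
        assert res.converged
        # generous: n=50 MLE of (-1, 0.5) within ~3 SE
        assert abs(res.beta0 + 1.0) < 0.8
        assert abs(res.beta[0] - 0.5) < 0.8

    def test_full_never_below_null(self, rng):
        for _ in range(10):
            x = rng.normal(size=(30, 2))
            counts = rng.integers(0, 3, size=30)
            if counts.sum() in (0, 60):
                continue
            full = fit_full(x, counts)
            null = fit_null(counts)
            assert full.loglik >= null.loglik - 1e-8

    def test_bernoulli_expansion_equivalence(self, rng):
        """The Binomial(2, p) fit equals logistic regression on each
        individual expanded into two binary allele observations."""
        for _ in range(20):
            n = rng.integers(20, 40)
            x = rng.normal(size=(n, 2))
            eta = -0.5 + x @ np.array([0.4, -0.3])
            counts = rng.binomial(2, 1 / (1 + np.exp(-eta)))
            if counts.sum() in (0, 2 * n):
                continue
            full = fit_full(x, counts)
            null = fit_null(counts)
            # expand: N_i successes and 2 - N_i failures per individual
            y = np.concatenate([np.repeat(1, c).tolist() + np.repeat(0, 2 - c).tolist()
                                for c in counts]).astype(float)
            xx = np.repeat(x, 2, axis=0)
            logit_full = sm.Logit(y, sm.add_constant(xx)).fit(disp=0)
            logit_null = sm.Logit(y, np.ones((2 * n, 1))).fit(disp=0)
            np.testing.assert_allclose(full.params, logit_full.params, atol=1e-6)
            assert 2 * (full.loglik - null.loglik) == pytest.approx(
                2 * (logit_full.llf - logit_null.llf), abs=1e-6
            )


class TestLRT:
    def test_chi2_reference_quantile(self):
        # a statistic at the chi2(2) 95th percentile gives p = 0.05
        assert stats.chi2.sf(5.991, 2) == pytest.approx(0.05, abs=1e-3)
        x = np.random.default_rng(0).normal(size=(30, 2))
        counts = np.random.default_rng(1).binomial(2, 0.4, 30)
        res = lrt_test(x, counts)
        assert res.pvalue == pytest.approx(stats.chi2.sf(res.statistic, 2), abs=1e-15)
        assert res.df == 2

    def test_all_constant_phenotypes_give_null_result(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lrt_test(np.ones((10, 2)), [0, 1, 2, 1, 0, 1, 1, 0, 2, 1])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0
        assert res.df == 0

    def test_one_constant_column_reduces_df(self):
        rng = np.random.default_rng(5)
        x = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        counts = rng.binomial(2, 0.4, 20)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lrt_test(x, counts)
        assert res.df == 1

    def test_statistic_nonnegative(self, rng):
        for _ in range(25):
            x = rng.normal(size=(25, 2))
            counts = rng.integers(0, 3, size=25)
            if counts.sum() in (0, 50):
                continue
            res = lrt_test(x, counts)
            assert res.statistic >= 0.0

    def test_location_shift_invariance(self, small_association_data):
        """Adding a constant to a phenotype column moves the intercept but
        not the LRT statistic."""
        x, counts = small_association_data
        base = lrt_test(x, counts)
        shifted = lrt_test(x + 7.5, counts)
        assert shifted.statistic == pytest.approx(base.statistic, abs=1e-6)
        assert shifted.fit_full.beta0 != pytest.approx(base.fit_full.beta0, abs=1e-3)

    def test_scale_invariance(self, small_association_data):
        """Rescaling a column inversely rescales its coefficient and leaves
        the LRT unchanged."""
        x, counts = small_association_data
        base = lrt_test(x, counts)
        scaled = lrt_test(x * 4.0, counts)
        assert scaled.statistic == pytest.approx(base.statistic, abs=1e-6)
        assert scaled.fit_full.beta[0] == pytest.approx(base.fit_full.beta[0] / 4.0,
                                                        abs=1e-6)

    def test_null_distribution_matches_chi2(self, rng):
        """Under genotype-independent phenotypes the LRT is chi-square(k)."""
        stats_ = []
        for _ in range(800):
            x = rng.normal(size=(100, 2))
            counts = rng.binomial(2, 0.3, 100)
            if counts.sum() in (0, 200):
                continue
            s, _, _, conv = _lrt_arrays(x, counts)
            if conv:
                stats_.append(s)
        ks = stats.kstest(stats_, stats.chi2(2).cdf)
        assert ks.pvalue > 0.01
        # empirical size at alpha = 0.05 within the Monte-Carlo band
        size = np.mean(np.array(stats_) > stats.chi2(2).ppf(0.95))
        band = 1.96 * math.sqrt(0.05 * 0.95 / len(stats_))
        assert abs(size - 0.05) < band + 1e-9


class TestModelObjects:
    def test_results_summary_mentions_components(self, small_association_data):
        x, counts = small_association_data
        pheno = PhenotypeVectorSet(x, component_labels=["SBP_PC1"])
        res = GenotypeBinomialModel(counts, pheno).fit()
        assert "SBP_PC1" in res.summary()
        assert "log-likelihood" in res.summary()

    def test_phenotype_set_validation(self):
        with pytest.raises(ValueError, match="missing"):
            PhenotypeVectorSet(np.array([[1.0], [np.nan], [2.0], [0.0]]))
        with pytest.raises(ValueError, match="n >= k\\+1"):
            PhenotypeVectorSet(np.ones((2, 2)))

    def test_genotype_counts_validation(self):
        with pytest.raises(ValueError, match="\\{0, 1, 2\\}"):
            GenotypeCounts(np.array([0, 1, 3]))
        geno = GenotypeCounts(np.array([0.0, np.nan, 2.0]))
        assert geno.n_nonmissing == 2
        np.testing.assert_array_equal(geno.observed(), [0, 2])
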