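"""Unit tests for the phenotype preprocessing pipeline."""

import math

import numpy as np
import pytest

from pleioscan import (
    CovariatePanel,
    DomainError,
    InsufficientDataError,
    LongitudinalPanel,
    MVNParams,
    PhenotypeVectorSpec,
    adjust_covariates,
    build_phenotype_vector,
    em_fit_mvn,
    impute_missing,
    impute_panel,
    log_transform,
    normality_diagnostic,
    pca_summarize,
)

from oracles import ols_residuals_normal_equations


def make_panel(values):
    values = np.asarray(values, dtype=float)
    n, T, p = values.shape
    return LongitudinalPanel(
        values,
        [f"i{j}" for j in range(n)],
        [f"t{j}" for j in range(T)],
        ["sbp", "dbp"][:p],
    )


class TestLogTransform:
    def test_log_identities(self):
        panel = make_panel([[[1.0], [math.e]], [[math.e ** 2], [1.0]]])
        out = log_transform(panel)
        np.testing.assert_allclose(out.values[:, :, 0], [[0, 1], [2, 0]], atol=1e-12)

    def test_missing_entries_pass_through(self):
        panel = make_panel([[[1.0], [np.nan]], [[2.0], [3.0]]])
        out = log_transform(panel)
        assert np.isnan(out.values[0, 1, 0])
        assert out.missing_mask.sum() == 1

    def test_nonpositive_value_names_individual(self):
        panel = make_panel([[[1.0], [0.0]], [[2.0], [3.0]]])
        with pytest.raises(DomainError, match="i0.*t1"):
            log_transform(panel)


class TestNormalityDiagnostic:
    def test_calibrated_on_normal_draws(self, rng):
        assert normality_diagnostic(rng.normal(size=5000)) > 0.05

    def test_rejects_exponential(self, rng):
        assert normality_diagnostic(rng.exponential(size=5000)) < 0.001

    def test_constant_sample_errors(self):
        with pytest.raises(DomainError, match="zero variance"):
            normality_diagnostic(np.full(10, 3.0))


def bivariate_mcar(rng, n=2000, rho=0.8, frac=0.2):
    X = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    mask = rng.random(n) < frac
    X_obs = X.copy()
    X_obs[mask, 1] = np.nan
    return X, X_obs


class TestEM:
    def test_complete_data_is_one_pass_mle(self, rng):
        X = rng.normal(size=(40, 3))
        params = em_fit_mvn(X)
        assert params.n_iter == 1
        np.testing.assert_allclose(params.mu, X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            params.sigma, np.cov(X, rowvar=False, bias=True), atol=1e-12
        )

    def test_loglik_trace_monotone(self, rng):
        _, X_obs = bivariate_mcar(rng, n=300)
        params = em_fit_mvn(X_obs)
        diffs = np.diff(params.loglik_trace)
        assert (diffs >= -1e-10).all()

    def test_recovers_correlation(self, rng):
        _, X_obs = bivariate_mcar(rng, n=2000, rho=0.8, frac=0.2)
        params = em_fit_mvn(X_obs)
        rho_hat = params.sigma[0, 1] / math.sqrt(params.sigma[0, 0] * params.sigma[1, 1])
        assert abs(rho_hat - 0.8) < 0.05

    def test_sparse_column_errors(self):
        X = np.full((10, 2), np.nan)
        X[:, 0] = 1.0
        X[0, 0] += 0.1  # keep column 0 non-constant
        X[0, 1] = 0.5
        with pytest.raises(InsufficientDataError):
            em_fit_mvn(X)

    def test_fully_missing_row_warns(self, rng):
        X = rng.normal(size=(30, 2))
        X[0, :] = np.nan
        with pytest.warns(UserWarning, match="no observed components"):
            em_fit_mvn(X)


class TestImpute:
    def test_complete_input_unchanged(self, rng):
        X = rng.normal(size=(20, 2))
        params = em_fit_mvn(X)
        np.testing.assert_array_equal(impute_missing(X, params), X)

    @pytest.mark.parametrize("rho", [0.0, 0.5, -0.7])
    def test_bivariate_conditional_mean_is_rho_z(self, rho):
        params = MVNParams([0.0, 0.0], [[1.0, rho], [rho, 1.0]], 1, [])
        X = np.array([[1.7, np.nan], [-0.4, np.nan]])
        out = impute_missing(X, params)
        np.testing.assert_allclose(out[:, 1], rho * X[:, 0], atol=1e-12)

    def test_fully_missing_row_filled_with_mean(self):
        params = MVNParams([2.0, -1.0], np.eye(2), 1, [])
        out = impute_missing(np.array([[np.nan, np.nan]]), params)
        np.testing.assert_allclose(out[0], [2.0, -1.0], atol=1e-12)

    def test_beats_column_mean_fill(self, rng):
        X_true, X_obs = bivariate_mcar(rng, n=2000, rho=0.8, frac=0.2)
        mask = np.isnan(X_obs)
        params = em_fit_mvn(X_obs)
        em_fill = impute_missing(X_obs, params)
        mean_fill = np.where(mask, np.nanmean(X_obs, axis=0), X_obs)
        mse_em = np.mean((em_fill[mask] - X_true[mask]) ** 2)
        mse_mean = np.mean((mean_fill[mask] - X_true[mask]) ** 2)
        assert mse_em < mse_mean

    def test_panel_single_pass_matches_full_em_roughly(self, rng):
        _, X_obs = bivariate_mcar(rng, n=500)
        panel = LongitudinalPanel(
            X_obs[:, :, None], [f"i{j}" for j in range(500)], ["t0", "t1"], ["sbp"],
        )
        full, _ = impute_panel(panel)
        single, _ = impute_panel(panel, single_pass=True)
        assert not np.isnan(full.values).any()
        assert not np.isnan(single.values).any()
        mask = np.isnan(X_obs)
        # both are conditional-mean fills; they should agree to first order
        assert np.corrcoef(full.values[:, :, 0][mask],
                           single.values[:, :, 0][mask])[0, 1] > 0.99


def make_covariates(rng, n, T, *, constant=False):
    if constant:
        age = np.full((n, T), 50.0)
        smoke = np.zeros((n, T))
        med = np.zeros((n, T))
    else:
        age = rng.normal(50, 8, size=(n, T))
        smoke = rng.binomial(1, 0.3, size=(n, T)).astype(float)
        med = rng.binomial(1, 0.4, size=(n, T)).astype(float)
    return CovariatePanel(age, smoke, med,
                          [f"i{j}" for j in range(n)], [f"t{j}" for j in range(T)])


class TestAdjustCovariates:
    def test_residuals_orthogonal_to_design(self, rng):
        n, T = 80, 3
        panel = make_panel(rng.normal(size=(n, T, 2)) + 5.0)
        covs = make_covariates(rng, n, T)
        residuals, kept = adjust_covariates(panel, covs)
        assert kept.size == n
        for trait in ("sbp", "dbp"):
            for t in range(T):
                r = residuals[trait][:, t]
                scale = np.abs(panel.values[:, t, 0]).max()
                assert abs(r.sum()) < 1e-8 * scale * n
                for cov in (covs.age, covs.smoking, covs.medication):
                    assert abs(r @ cov[:, t]) < 1e-6 * scale * n

    def test_individuals_with_any_missing_covariate_dropped(self, rng):
        n, T = 30, 2
        panel = make_panel(rng.normal(size=(n, T, 2)) + 5.0)
        covs = make_covariates(rng, n, T)
        covs.age[3, 1] = np.nan
        covs.medication[10, 0] = np.nan
        residuals, kept = adjust_covariates(panel, covs)
        assert set(kept) == set(range(n)) - {3, 10}
        assert residuals["sbp"].shape == (n - 2, T)

    def test_constant_covariates_give_centered_values(self, rng):
        n, T = 25, 2
        panel = make_panel(rng.normal(size=(n, T, 2)) + 5.0)
        covs = make_covariates(rng, n, T, constant=True)
        with pytest.warns(UserWarning, match="constant"):
            residuals, _ = adjust_covariates(panel, covs)
        expected = panel.values[:, :, 0] - panel.values[:, :, 0].mean(axis=0)
        np.testing.assert_allclose(residuals["sbp"], expected, atol=1e-10)

    def test_matches_normal_equations_on_small_dataset(self, rng):
        n, T = 6, 1
        y = np.array([5.1, 4.9, 6.2, 5.5, 4.7, 5.9])
        panel = make_panel(y[:, None, None])
        panel.trait_labels[:] = ["sbp"]
        age = np.array([40.0, 55.0, 61.0, 47.0, 52.0, 58.0])
        smoke = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 1.0])
        med = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        covs = CovariatePanel(age[:, None], smoke[:, None], med[:, None],
                              panel.individual_ids, ["t0"])
        residuals, _ = adjust_covariates(panel, covs)
        expected = ols_residuals_normal_equations(
            y, np.column_stack([age, smoke, med])
        )
        np.testing.assert_allclose(residuals["sbp"][:, 0], expected, atol=1e-10)


class TestPCA:
    def test_rank_one_structure_explains_everything(self, rng):
        base = rng.normal(size=100)
        R = np.column_stack([base, 2 * base, -0.5 * base])
        scores, ve = pca_summarize(R, 1)
        assert ve[0] == pytest.approx(1.0, abs=1e-12)
        assert scores.shape == (100, 1)

    def test_variance_fractions_sum_to_one(self, rng):
        R = rng.normal(size=(50, 4))
        _, ve = pca_summarize(R, 2)
        assert ve.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(ve) <= 1e-12).all()

    def test_known_eigenvalue_ratios(self, rng):
        sd = np.sqrt(np.array([4.0, 2.0, 1.0, 1.0]))
        R = rng.normal(size=(20000, 4)) * sd
        _, ve = pca_summarize(R, 2)
        np.testing.assert_allclose(ve, [0.5, 0.25, 0.125, 0.125], atol=0.02)

    def test_scores_centered_and_uncorrelated(self, rng):
        R = rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4))
        scores, _ = pca_summarize(R, 3)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        cov = scores.T @ scores
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(cov)).max()

    def test_too_many_components_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            pca_summarize(rng.normal(size=(30, 3)), 4)


class TestBuildPhenotypeVector:
    @pytest.fixture
    def residuals(self, rng):
        return rng.normal(size=(60, 4)), rng.normal(size=(60, 4))

    def test_t1_is_sbp_passthrough(self, residuals):
        sbp, dbp = residuals
        out = build_phenotype_vector(sbp, dbp, PhenotypeVectorSpec("T1"))
        np.testing.assert_array_equal(out.values, sbp)
        assert out.component_labels == ["SBP_t1", "SBP_t2", "SBP_t3", "SBP_t4"]

    def test_t5_concatenates_pc_scores(self, residuals):
        sbp, dbp = residuals
        out = build_phenotype_vector(sbp, dbp, PhenotypeVectorSpec("T5", 2))
        assert out.k == 4
        assert out.component_labels == ["SBP_PC1", "SBP_PC2", "DBP_PC1", "DBP_PC2"]
        s_scores, _ = pca_summarize(sbp, 2)
        np.testing.assert_allclose(out.values[:, :2], s_scores, atol=1e-12)

    @pytest.mark.parametrize("mode,k", [("T2", 4), ("T3", 2), ("T4", 2)])
    def test_modes_have_documented_width(self, residuals, mode, k):
        sbp, dbp = residuals
        out = build_phenotype_vector(sbp, dbp, PhenotypeVectorSpec(mode))
        assert out.k == k

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="T6"):
            PhenotypeVectorSpec("T6")
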