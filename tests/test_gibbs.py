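"""Oracle checks for the Gibbs sampler's conditional distributions.

Each conjugate block is compared against its closed form (truncated-normal
moments, conjugate normal posteriors, inverse-gamma and inverse-Wishart
means, least-squares agreement under near-flat priors) on fixed inputs.
"""

import numpy as np
import pytest

from pathsem import (  # noqa: F401
    GenerativeParams,
    McmcConfig,
    ParameterSet,
    build_default_spec,
    fit,
    impute_binary_propensity,
    simulate_cohort,
)
from pathsem.errors import ValidationError
from pathsem.gibbs import (
    SamplerState,
    update_factor_covariance,
    update_factor_scores,
    update_measurement_params,
    update_residual_variances,
    update_structural_params,
)
from pathsem.model_spec import CONTINUOUS, CovariateDef, IndicatorDef, ModelSpec

N_MC = 100_000


def single_factor_spec(n_ind=1, covariates=(), binary_outcome="event"):
    inds = tuple(
        IndicatorDef(f"y{j}", "f", CONTINUOUS, 1.0 if j == 0 else None)
        for j in range(n_ind)
    )
    return ModelSpec(
        factors=("f",),
        indicators=inds,
        covariates=tuple(CovariateDef(c) for c in covariates),
        outcome=binary_outcome,
        outcome_label="total_cvd",
    )


def make_state(spec, *, lam, psi, Phi, ystar, xi, mu=None, gamma=None,
               beta=None, eta=None, intercept=0.0):
    n = ystar.shape[0]
    k = spec.n_factors
    params = ParameterSet(
        mu=np.zeros(spec.n_indicators) if mu is None else np.asarray(mu, float),
        lam=np.asarray(lam, float),
        psi=np.asarray(psi, float),
        Phi=np.atleast_2d(np.asarray(Phi, float)),
        gamma=np.zeros(k) if gamma is None else np.asarray(gamma, float),
        beta=np.zeros(len(spec.covariates)) if beta is None else np.asarray(beta, float),
        outcome_intercept=intercept,
    )
    return SamplerState(
        params=params,
        xi=np.asarray(xi, float).reshape(n, k),
        ystar=np.asarray(ystar, float).reshape(n, spec.n_indicators),
        eta=np.zeros(n) if eta is None else np.asarray(eta, float),
    )


class TestTruncatedNormalAugmentation:
    def test_positive_truncation_mean(self):
        rng = np.random.default_rng(0)
        draws = impute_binary_propensity(np.ones(N_MC), np.zeros(N_MC), rng)
        assert (draws > 0).all()
        # E[Z | Z > 0] = sqrt(2/pi)
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_negative_truncation_by_symmetry(self):
        rng = np.random.default_rng(1)
        draws = impute_binary_propensity(np.zeros(N_MC), np.zeros(N_MC), rng)
        assert (draws <= 0).all()
        assert draws.mean() == pytest.approx(-np.sqrt(2 / np.pi), abs=0.01)

    def test_negligible_truncation_at_large_predictor(self):
        rng = np.random.default_rng(2)
        draws = impute_binary_propensity(np.ones(N_MC), np.full(N_MC, 10.0), rng)
        assert draws.mean() == pytest.approx(10.0, abs=0.01)
        assert draws.std() == pytest.approx(1.0, abs=0.02)

    def test_deep_tail_is_finite_and_signed(self):
        # observation in conflict with an extreme predictor: the draw must
        # still respect the observed sign without overflowing
        rng = np.random.default_rng(3)
        draws = impute_binary_propensity(np.ones(1000), np.full(1000, -45.0), rng)
        assert np.isfinite(draws).all()
        assert (draws > 0).all()

    def test_sign_always_consistent_with_observation(self):
        rng = np.random.default_rng(4)
        obs = rng.integers(0, 2, 5000).astype(float)
        lin = rng.normal(0, 3, 5000)
        draws = impute_binary_propensity(obs, lin, rng)
        assert ((draws > 0) == (obs == 1)).all()

    def test_non_binary_observation_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValidationError):
            impute_binary_propensity(np.array([0.0, 2.0]), np.zeros(2), rng)


class TestFactorScoreConditional:
    """One factor, one continuous indicator, lam=1, psi=1, Phi=1: the
    conditional is N(y/2, 1/2)."""

    def _draws(self, y, include_outcome=False):
        spec = single_factor_spec()
        rng = np.random.default_rng(10)
        n = N_MC
        state = make_state(
            spec, lam=[1.0], psi=[1.0], Phi=[[1.0]],
            ystar=np.full((n, 1), float(y)), xi=np.zeros((n, 1)),
        )
        C = np.empty((n, 0))
        return update_factor_scores(state, spec, C, rng, include_outcome=include_outcome)

    def test_conditional_at_y0(self):
        xi = self._draws(0.0)
        assert xi.mean() == pytest.approx(0.0, abs=0.01)
        assert xi.var() == pytest.approx(0.5, rel=0.03)

    def test_conditional_at_y2(self):
        xi = self._draws(2.0)
        assert xi.mean() == pytest.approx(1.0, abs=0.01)
        assert xi.var() == pytest.approx(0.5, rel=0.03)

    def test_no_information_returns_prior(self):
        # loading 0 and gamma 0: conditional equals the prior N(0, Phi)
        spec = single_factor_spec()
        rng = np.random.default_rng(11)
        n = N_MC
        state = make_state(
            spec, lam=[0.0], psi=[1.0], Phi=[[2.0]],
            ystar=np.full((n, 1), 5.0), xi=np.zeros((n, 1)),
        )
        xi = update_factor_scores(state, spec, np.empty((n, 0)), rng)
        assert xi.mean() == pytest.approx(0.0, abs=0.02)
        assert xi.var() == pytest.approx(2.0, rel=0.03)


class TestMeasurementConditional:
    def test_reference_loading_never_moves(self, spec, small_cohort):
        cfg = McmcConfig(n_chains=1, n_iter=60, n_burnin=10, seed=2)
        draws = fit(spec, small_cohort, cfg, standardize=False)
        for j, ind in enumerate(spec.indicators):
            if ind.is_reference:
                assert (draws.lam[:, :, j] == 1.0).all()

    def test_degenerate_prior_collapses_to_zero(self):
        spec = single_factor_spec(n_ind=2)
        rng = np.random.default_rng(12)
        n = 500
        state = make_state(
            spec, lam=[1.0, 0.8], psi=[1.0, 1.0], Phi=[[1.0]],
            ystar=rng.normal(3.0, 1.0, (n, 2)), xi=rng.normal(0, 1, (n, 1)),
        )
        cfg = McmcConfig(prior_loc_var=1e-12)
        mus, lams = [], []
        for _ in range(200):
            mu, lam = update_measurement_params(state, spec, cfg, rng)
            mus.append(mu)
            lams.append(lam[1])
        assert np.abs(np.mean(mus, axis=0)).max() < 1e-3
        assert abs(np.mean(lams)) < 1e-3

    def test_flat_prior_matches_least_squares(self):
        spec = single_factor_spec(n_ind=2)
        rng = np.random.default_rng(13)
        n = 5000
        xi = rng.normal(0, 1, (n, 1))
        psi_true = 0.5
        y1 = 0.3 + 0.8 * xi[:, 0] + rng.normal(0, np.sqrt(psi_true), n)
        ystar = np.column_stack([np.zeros(n), y1])
        state = make_state(
            spec, lam=[1.0, 0.0], psi=[1.0, psi_true], Phi=[[1.0]],
            ystar=ystar, xi=xi,
        )
        cfg = McmcConfig(prior_loc_var=1e6)
        draws = np.array(
            [update_measurement_params(state, spec, cfg, rng)[1][1] for _ in range(2000)]
        )
        X = np.column_stack([np.ones(n), xi[:, 0]])
        slope_ls = np.linalg.lstsq(X, y1, rcond=None)[0][1]
        se = np.sqrt(psi_true / (xi[:, 0] ** 2).sum())
        assert abs(draws.mean() - slope_ls) < 3 * se / np.sqrt(len(draws) / 10)


class TestResidualVarianceConditional:
    def test_prior_reproduction_at_n0(self):
        spec = single_factor_spec()
        rng = np.random.default_rng(14)
        state = make_state(
            spec, lam=[1.0], psi=[1.0], Phi=[[1.0]],
            ystar=np.empty((0, 1)), xi=np.empty((0, 1)),
        )
        cfg = McmcConfig(prior_psi_shape=2.0, prior_psi_rate=1.0)
        draws = np.array(
            [update_residual_variances(state, spec, cfg, rng)[0] for _ in range(N_MC // 2)]
        )
        # inverse-gamma(2, 1) mean = b0 / (a0 - 1) = 1
        assert draws.mean() == pytest.approx(1.0, rel=0.05)

    def test_posterior_mean_formula(self):
        # rss = 100 at n = 100 with IG(2, 1) prior: mean (1 + 50)/(2 + 50 - 1) = 1
        spec = single_factor_spec()
        rng = np.random.default_rng(15)
        n = 100
        state = make_state(
            spec, lam=[1.0], psi=[1.0], Phi=[[1.0]],
            ystar=np.ones((n, 1)), xi=np.zeros((n, 1)), mu=[0.0],
        )
        cfg = McmcConfig(prior_psi_shape=2.0, prior_psi_rate=1.0)
        draws = np.array(
            [update_residual_variances(state, spec, cfg, rng)[0] for _ in range(20000)]
        )
        assert draws.mean() == pytest.approx(1.0, rel=0.02)

    def test_binary_indicator_variance_fixed(self, spec, small_cohort):
        cfg = McmcConfig(n_chains=1, n_iter=60, n_burnin=10, seed=3)
        draws = fit(spec, small_cohort, cfg, standardize=False)
        for j, ind in enumerate(spec.indicators):
            if ind.scale != CONTINUOUS:
                assert (draws.psi[:, :, j] == 1.0).all()


class TestFactorCovarianceConditional:
    def test_prior_reproduction_at_n0(self):
        # use nu0 = 12 so the prior mean S0/(nu0 - 6 - 1) = I/5 has finite
        # variance and the MC average converges
        rng = np.random.default_rng(16)
        state = SamplerState(
            params=None, xi=np.empty((0, 6)), ystar=np.empty((0, 0)), eta=np.empty(0)
        )
        cfg = McmcConfig(prior_phi_df=12.0)
        draws = np.mean(
            [update_factor_covariance(state, cfg, rng) for _ in range(20000)], axis=0
        )
        np.testing.assert_allclose(draws, np.eye(6) / 5.0, atol=0.02)

    def test_posterior_mean_with_fixed_scores(self):
        # Xi'Xi = 1000 I, nu0 = 8, S0 = I, n = 1000: mean = 1001 I / 1001 = I
        rng = np.random.default_rng(17)
        xi = np.zeros((1000, 6))
        for a in range(6):
            xi[a, a] = np.sqrt(1000.0)  # first 6 rows carry the whole cross product
        state = SamplerState(params=None, xi=xi, ystar=np.empty((1000, 0)), eta=np.empty(1000))
        cfg = McmcConfig(prior_phi_df=8.0)
        draws = np.mean(
            [update_factor_covariance(state, cfg, rng) for _ in range(3000)], axis=0
        )
        np.testing.assert_allclose(draws, np.eye(6), atol=0.02)

    def test_draws_symmetric_positive_definite(self):
        rng = np.random.default_rng(18)
        xi = rng.normal(0, 1, (50, 6))
        state = SamplerState(params=None, xi=xi, ystar=np.empty((50, 0)), eta=np.empty(50))
        cfg = McmcConfig()
        for _ in range(100):
            Phi = update_factor_covariance(state, cfg, rng)
            np.testing.assert_allclose(Phi, Phi.T, atol=1e-12)
            assert np.linalg.eigvalsh(Phi).min() > 0


class TestStructuralConditional:
    def test_flat_prior_matches_least_squares(self):
        spec = single_factor_spec(covariates=("x1",))
        rng = np.random.default_rng(19)
        n = 4000
        xi = rng.normal(0, 1, (n, 1))
        C = rng.normal(0, 1, (n, 1))
        eta = 0.5 + 0.3 * C[:, 0] + 0.7 * xi[:, 0] + rng.normal(0, 1, n)
        state = make_state(
            spec, lam=[1.0], psi=[1.0], Phi=[[1.0]],
            ystar=np.zeros((n, 1)), xi=xi, eta=eta, beta=[0.0],
        )
        cfg = McmcConfig(prior_loc_var=1e6)
        draws = np.array(
            [
                np.concatenate([[a], b, g])
                for a, b, g in (
                    update_structural_params(state, spec, C, cfg, rng)
                    for _ in range(2000)
                )
            ]
        )
        import statsmodels.api as sm

        W = np.column_stack([np.ones(n), C, xi])
        ols = sm.OLS(eta, W).fit()
        se = np.sqrt(np.diag(np.linalg.inv(W.T @ W)))
        assert np.all(
            np.abs(draws.mean(axis=0) - ols.params) < 3 * se / np.sqrt(len(draws) / 20)
        )


class TestFitContract:
    def test_bookkeeping_single_retained_draw(self, spec, small_cohort):
        cfg = McmcConfig(n_chains=2, n_iter=11, n_burnin=10, thin=1, seed=1)
        draws = fit(spec, small_cohort, cfg, standardize=False)
        assert draws.n_retained == 1
        assert draws.mu.shape[:2] == (2, 1)

    def test_reproducibility(self, spec, small_cohort):
        cfg = McmcConfig(n_chains=2, n_iter=80, n_burnin=20, seed=9)
        a = fit(spec, small_cohort, cfg, standardize=False)
        b = fit(spec, small_cohort, cfg, standardize=False)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.Phi, b.Phi)
        np.testing.assert_array_equal(a.lam, b.lam)

    def test_missing_values_rejected(self, spec, small_cohort):
        import pandas as pd

        from pathsem.synthetic import CohortTable

        df = small_cohort.df.copy()
        df.iloc[3, 5] = np.nan
        broken = CohortTable(df=df, spec=spec)
        with pytest.raises(ValidationError, match="missing"):
            fit(spec, broken, McmcConfig(n_iter=20, n_burnin=10))

    def test_bad_binary_value_rejected(self, spec, small_cohort):
        from pathsem.synthetic import CohortTable

        df = small_cohort.df.copy()
        df.loc[0, "dm"] = 2.0
        broken = CohortTable(df=df, spec=spec)
        with pytest.raises(ValidationError, match="dm"):
            fit(spec, broken, McmcConfig(n_iter=20, n_burnin=10))

    def test_single_factor_recovery(self):
        """Known truth lam=(1, 0.8, 0.5), psi=0.5, Phi=1 at n=2000: every
        free parameter recovered within 3 posterior SDs."""
        spec = single_factor_spec(n_ind=3)
        truth = GenerativeParams(
            mu=np.array([0.0, 0.2, -0.1]),
            lam=np.array([1.0, 0.8, 0.5]),
            psi=np.array([0.5, 0.5, 0.5]),
            Phi=np.array([[1.0]]),
            gamma=np.array([0.4]),
            beta=np.zeros(0),
            outcome_intercept=-1.0,
        )
        cohort = simulate_cohort(spec, truth, n=2000, seed=30)
        cfg = McmcConfig(n_chains=2, n_iter=1500, n_burnin=500, seed=31)
        draws = fit(spec, cohort, cfg, standardize=False)
        from pathsem import flatten_free, free_parameter_names

        chains = draws.parameter_chains()
        for name, tv in zip(free_parameter_names(spec), flatten_free(truth, spec)):
            pooled = chains[name].reshape(-1)
            assert abs(pooled.mean() - tv) < 3.5 * pooled.std(ddof=1), name
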