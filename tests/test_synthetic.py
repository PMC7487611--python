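"""Generative correctness of the synthetic cohort module."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from pathsem import (
    OUTCOME_PREVALENCE,
    GenerativeParams,
    build_default_spec,
    calibrate_outcome_intercept,
    default_true_params,
    simulate_cohort,
)
from pathsem.errors import RuntimeFailure, ValidationError
from pathsem.model_spec import CONTINUOUS


class TestDefaultTruth:
    def test_structural_coefficients_match_published_values(self, spec):
        params = default_true_params(spec)
        np.testing.assert_allclose(
            params.gamma, [0.26, 0.24, 0.13, 0.10, -0.17, -0.16]
        )

    def test_published_loadings(self, spec):
        params = default_true_params(spec)
        names = list(spec.indicator_names)
        assert params.lam[names.index("wc")] == 0.78
        assert params.lam[names.index("bp")] == 0.74
        assert params.lam[names.index("tg")] == 0.84
        # reference loadings all fixed at one
        for j, ind in enumerate(spec.indicators):
            if ind.is_reference:
                assert params.lam[j] == 1.0

    def test_published_latent_covariances(self, spec):
        params = default_true_params(spec)
        i = spec.factor_index("lipids")
        j = spec.factor_index("quality_of_life")
        assert params.Phi[i, j] == pytest.approx(-0.92)
        assert params.Phi[i, spec.factor_index("anthropometric")] == pytest.approx(0.99)

    @pytest.mark.parametrize("label", ["total_cvd", "stroke", "acs", "fatal_cvd"])
    def test_truth_is_valid_and_pd_for_every_outcome(self, label):
        s = build_default_spec(label)
        p = default_true_params(s)
        p.validate(s)
        assert np.linalg.eigvalsh(p.Phi).min() > 0


class TestSimulate:
    def test_empty_cohort_has_all_columns(self, spec, true_params):
        table = simulate_cohort(spec, true_params, n=0, seed=0)
        assert len(table.df) == 0
        assert list(table.df.columns) == list(spec.column_order)
        assert len(table.df.columns) == 22

    def test_determinism_bit_identical(self, spec, true_params):
        a = simulate_cohort(spec, true_params, n=500, seed=123)
        b = simulate_cohort(spec, true_params, n=500, seed=123)
        pd.testing.assert_frame_equal(a.df, b.df)
        np.testing.assert_array_equal(a.truth.xi, b.truth.xi)

    def test_different_seed_differs(self, spec, true_params):
        a = simulate_cohort(spec, true_params, n=100, seed=1)
        b = simulate_cohort(spec, true_params, n=100, seed=2)
        assert not a.df.equals(b.df)

    def test_negative_n_rejected(self, spec, true_params):
        with pytest.raises(ValidationError):
            simulate_cohort(spec, true_params, n=-1, seed=0)

    def test_non_pd_phi_rejected(self, spec, true_params):
        bad = GenerativeParams.from_dict(true_params.to_dict())
        bad.Phi = np.full((6, 6), 1.0)  # rank one, singular
        with pytest.raises(ValidationError, match="[Pp]hi|positive definite"):
            simulate_cohort(spec, bad, n=10, seed=0)

    def test_moment_match_identity_case(self, spec, true_params):
        """With free loadings 0, Phi = I, psi = 1, continuous indicators are
        nearly independent: sample covariance approaches Lam Phi Lam' + Psi."""
        p = GenerativeParams.from_dict(true_params.to_dict())
        p.Phi = np.eye(6)
        for j, ind in enumerate(spec.indicators):
            if not ind.is_reference:
                p.lam[j] = 0.0
            if ind.scale == CONTINUOUS:
                p.psi[j] = 1.0
                p.mu[j] = 0.0
        n = 200_000
        table = simulate_cohort(spec, p, n=n, seed=7)
        cont = [i.name for i in spec.indicators if i.scale == CONTINUOUS and not i.is_reference]
        S = np.cov(table.df[cont].to_numpy(), rowvar=False)
        off = S - np.diag(np.diag(S))
        assert np.abs(off).max() < 0.01
        np.testing.assert_allclose(np.diag(S), 1.0, atol=0.02)

    def test_moment_match_full_truth(self, spec, true_params):
        """Large-n sample covariance of continuous indicators converges to
        the closed form Lam Phi Lam' + Psi (within 3 MC standard errors)."""
        n = 200_000
        table = simulate_cohort(spec, true_params, n=n, seed=8)
        cont_idx = [j for j, i in enumerate(spec.indicators) if i.scale == CONTINUOUS]
        names = [spec.indicators[j].name for j in cont_idx]
        fidx = spec.indicator_factor_index()
        Lmat = np.zeros((len(cont_idx), 6))
        for r, j in enumerate(cont_idx):
            Lmat[r, fidx[j]] = true_params.lam[j]
        Sigma = Lmat @ true_params.Phi @ Lmat.T + np.diag(
            [true_params.psi[j] for j in cont_idx]
        )
        S = np.cov(table.df[names].to_numpy(), rowvar=False)
        # MC standard error of a covariance entry is ~ sqrt((s_ii s_jj + s_ij^2)/n)
        se = np.sqrt(
            (np.outer(np.diag(Sigma), np.diag(Sigma)) + Sigma**2) / n
        )
        assert np.all(np.abs(S - Sigma) < 3.5 * se)

    def test_binary_marginals_match_probit_formula(self, spec, true_params):
        n = 200_000
        table = simulate_cohort(spec, true_params, n=n, seed=9)
        fidx = spec.indicator_factor_index()
        for j, ind in enumerate(spec.indicators):
            if ind.scale == CONTINUOUS:
                continue
            var = true_params.lam[j] ** 2 * true_params.Phi[fidx[j], fidx[j]] + 1.0
            expect = ndtr(true_params.mu[j] / np.sqrt(var))
            got = table.df[ind.name].mean()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(got - expect) < 4 * se, ind.name

    def test_outcome_prevalence_near_published_rate(self, spec, true_params):
        target = OUTCOME_PREVALENCE["total_cvd"]
        n = 3161
        se = np.sqrt(target * (1 - target) / n)
        hits = 0
        for seed in range(5):
            table = simulate_cohort(spec, true_params, n=n, seed=seed)
            if abs(table.df[spec.outcome].mean() - target) < 2 * se:
                hits += 1
        assert hits >= 4  # 2-SE band should hold for nearly all seeds


class TestCalibration:
    def test_null_model_symmetric(self, spec, true_params):
        p = GenerativeParams.from_dict(true_params.to_dict())
        p.gamma = np.zeros(6)
        p.beta = np.zeros(3)
        out = calibrate_outcome_intercept(spec, p, 0.5, n_mc=50_000, seed=0)
        assert abs(out.outcome_intercept) < 0.02

    def test_null_model_matches_normal_quantile(self, spec, true_params):
        p = GenerativeParams.from_dict(true_params.to_dict())
        p.gamma = np.zeros(6)
        p.beta = np.zeros(3)
        out = calibrate_outcome_intercept(spec, p, 0.129, n_mc=50_000, seed=0)
        assert out.outcome_intercept == pytest.approx(ndtri(0.129), abs=0.02)

    def test_self_consistency_by_resimulation(self, spec, true_params):
        n = 100_000
        table = simulate_cohort(spec, true_params, n=n, seed=21)
        prev = table.df[spec.outcome].mean()
        assert abs(prev - OUTCOME_PREVALENCE["total_cvd"]) < 0.006

    def test_invalid_target_rejected(self, spec, true_params):
        with pytest.raises(ValidationError):
            calibrate_outcome_intercept(spec, true_params, 1.5)

    def test_unreachable_target_rejected(self, spec, true_params):
        p = GenerativeParams.from_dict(true_params.to_dict())
        p.gamma = np.zeros(6)
        p.beta = np.zeros(3)
        with pytest.raises(RuntimeFailure):
            # requires an intercept below -10 (the normal quantile of 1e-30)
            calibrate_outcome_intercept(spec, p, 1e-30, n_mc=10_000, seed=0)
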