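"""Gibbs sampler for the latent-variable probit structural equation model.

Every full conditional is conjugate once binary observations are augmented
with truncated-normal propensities (classic probit augmentation), so the
sampler is pure Gibbs — no Metropolis steps, no tuning.  One iteration
cycles, in fixed order:

1. truncated-normal augmentation of every binary indicator and the outcome,
2. factor scores ``xi_i`` from their exact multivariate-normal conditional,
3. measurement intercepts and free loadings (per-indicator normal
   regression), reference loadings stay fixed at 1,
4. residual variances of continuous indicators (inverse-gamma); binary
   residual variances stay fixed at 1 (probit identification),
5. latent covariance ``Phi`` (inverse-Wishart),
6. structural block (outcome intercept, covariate betas, factor gammas)
   from one joint normal conditional with outcome residual variance fixed
   at 1.

Priors are weakly informative and conjugate: N(0, v0) on every location
parameter (v0 = 100 by default), inverse-gamma(a0, b0) on residual
variances, inverse-Wishart(nu0, S0) on Phi.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .errors import RuntimeFailure, ValidationError
from .model_spec import BINARY, CONTINUOUS, ModelSpec, require_valid
from .params import ParameterSet
from .synthetic import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "SamplerState",
    "PosteriorDraws",
    "fit",
    "impute_binary_propensity",
    "update_factor_scores",
    "update_measurement_params",
    "update_residual_variances",
    "update_factor_covariance",
    "update_structural_params",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings and prior hyperparameters.

    Defaults: 2 chains of 6,000 iterations with 1,000 burn-in, no thinning;
    N(0, 10^2) priors on location parameters, inverse-gamma(2, 1) on
    residual variances, inverse-Wishart(8, I) on the latent covariance.
    """

    n_chains: int = 2
    n_iter: int = 6000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0
    prior_loc_var: float = 100.0      # v0
    prior_psi_shape: float = 2.0      # a0
    prior_psi_rate: float = 1.0       # b0
    prior_phi_df: Optional[float] = None   # nu0; default k + 2
    prior_phi_scale: Optional[np.ndarray] = None  # S0; default identity
    xi_snapshot_count: int = 100      # factor-score snapshots kept per chain

    def validate(self, k: int) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValidationError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.prior_loc_var <= 0:
            raise ValidationError("prior_loc_var must be > 0")
        nu0 = self.phi_df(k)
        if nu0 <= k - 1:
            raise ValidationError(f"inverse-Wishart df must exceed k-1 = {k - 1}")
        S0 = self.phi_scale(k)
        if np.linalg.eigvalsh(S0).min() <= 0:
            raise ValidationError("inverse-Wishart scale matrix must be positive definite")

    def phi_df(self, k: int) -> float:
        return float(self.prior_phi_df) if self.prior_phi_df is not None else k + 2.0

    def phi_scale(self, k: int) -> np.ndarray:
        if self.prior_phi_scale is not None:
            return np.asarray(self.prior_phi_scale, dtype=float)
        return np.eye(k)

    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    def chain_seed(self, chain: int) -> int:
        """Deterministic per-chain stream: seed + chain * 10^6."""
        return int(self.seed) + chain * 1_000_000


@dataclass
class SamplerState:
    """Mutable state of one chain: parameters, factor scores, propensities."""

    params: ParameterSet
    xi: np.ndarray              # (n, k)
    ystar: np.ndarray           # (n, p) indicators; continuous cols = observed data
    eta: np.ndarray             # (n,) outcome propensity


# ---------------------------------------------------------------------------
# Truncated-normal augmentation
# ---------------------------------------------------------------------------


def _truncnorm_positive(mean: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw from N(mean, 1) truncated to (0, inf) via the upper-tail inverse CDF.

    ``u`` is uniform on [0, 1).  Works to machine accuracy for means as low
    as ~-37; beyond that the tail mass underflows and an exponential tail
    approximation around the truncation point is used instead.
    """
    a = -mean                      # truncation point in standard units
    p = ndtr(mean)                 # upper-tail mass P(Z > a)
    safe = p > 0
    x = np.empty_like(np.asarray(mean, dtype=float))
    # survival-function inversion: solve P(Z > x) = (1-u) * p
    q = (1.0 - u) * np.where(safe, p, 1.0)
    x[safe] = -ndtri(q[safe])
    if not safe.all():
        aa = a[~safe]
        x[~safe] = aa - np.log1p(-u[~safe]) / aa
    return mean + x


def impute_binary_propensity(
    observed: np.ndarray,
    linear_predictor: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw latent propensities consistent with binary observations.

    For ``observed == 1`` the draw comes from N(linear_predictor, 1)
    truncated to (0, inf); for ``observed == 0`` from the complementary
    half-line (-inf, 0].
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    m = np.broadcast_to(np.asarray(linear_predictor, dtype=float), observed.shape)
    if not np.isin(observed, (0.0, 1.0)).all():
        raise ValidationError("observed values must be binary 0/1")
    u = rng.random(observed.shape)
    pos = _truncnorm_positive(np.where(observed == 1, m, -m), u)
    return np.where(observed == 1, pos, -pos)


# ---------------------------------------------------------------------------
# Conditional updates
# ---------------------------------------------------------------------------


def update_factor_scores(
    state: SamplerState,
    spec: ModelSpec,
    C: np.ndarray,
    rng: np.random.Generator,
    include_outcome: bool = True,
) -> np.ndarray:
    """Draw all factor scores from their exact multivariate-normal conditional.

    The (shared) posterior precision is ``inv(Phi) + Lam' inv(Psi) Lam
    [+ gamma gamma']``; subject-specific means solve the corresponding
    normal equations.
    """
    p = state.params
    k = spec.n_factors
    n = state.xi.shape[0]
    fidx = np.asarray(spec.indicator_factor_index())

    Lmat = np.zeros((spec.n_indicators, k))
    Lmat[np.arange(spec.n_indicators), fidx] = p.lam
    A = Lmat / p.psi[:, None]                       # Psi^-1 Lam

    try:
        Phi_chol = cholesky(p.Phi, lower=True)
    except np.linalg.LinAlgError as exc:
        raise RuntimeFailure("latent covariance became singular") from exc
    Phi_inv = cho_solve((Phi_chol, True), np.eye(k))
    P = Phi_inv + Lmat.T @ A
    if include_outcome:
        P = P + np.outer(p.gamma, p.gamma)

    B = (state.ystar - p.mu) @ A                    # (n, k)
    if include_outcome:
        resid = state.eta - p.outcome_intercept - C @ p.beta
        B = B + np.outer(resid, p.gamma)

    try:
        L = cholesky(P, lower=True)
    except np.linalg.LinAlgError as exc:
        raise RuntimeFailure("factor-score precision matrix is singular") from exc
    mean = cho_solve((L, True), B.T).T
    noise = solve_triangular(L, rng.standard_normal((k, n)), lower=True, trans="T").T
    return mean + noise


def update_measurement_params(
    state: SamplerState,
    spec: ModelSpec,
    config: McmcConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw intercepts and free loadings; fixed loadings are untouched."""
    p = state.params
    v0 = config.prior_loc_var
    fidx = spec.indicator_factor_index()
    n = state.xi.shape[0]
    mu = p.mu.copy()
    lam = p.lam.copy()
    for j, ind in enumerate(spec.indicators):
        w = state.ystar[:, j]
        x = state.xi[:, fidx[j]]
        psi_j = p.psi[j]
        if ind.is_reference:
            resid = w - lam[j] * x
            prec = n / psi_j + 1.0 / v0
            mean = resid.sum() / psi_j / prec
            mu[j] = mean + rng.standard_normal() / np.sqrt(prec)
        else:
            sx, sxx = x.sum(), x @ x
            XtX = np.array([[n, sx], [sx, sxx]])
            Xtw = np.array([w.sum(), x @ w])
            prec = XtX / psi_j + np.eye(2) / v0
            Lp = cholesky(prec, lower=True)
            mean = cho_solve((Lp, True), Xtw / psi_j)
            draw = mean + solve_triangular(Lp, rng.standard_normal(2), lower=True, trans="T")
            mu[j], lam[j] = draw
    return mu, lam


def update_residual_variances(
    state: SamplerState,
    spec: ModelSpec,
    config: McmcConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-gamma draws for continuous indicators; binary stay at 1."""
    p = state.params
    fidx = spec.indicator_factor_index()
    n = state.xi.shape[0]
    psi = p.psi.copy()
    for j, ind in enumerate(spec.indicators):
        if ind.scale != CONTINUOUS:
            continue
        resid = state.ystar[:, j] - p.mu[j] - p.lam[j] * state.xi[:, fidx[j]]
        shape = config.prior_psi_shape + n / 2.0
        rate = config.prior_psi_rate + 0.5 * resid @ resid
        psi[j] = rate / rng.gamma(shape)
    return psi


def update_factor_covariance(
    state: SamplerState,
    config: McmcConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-Wishart draw for the latent covariance."""
    k = state.xi.shape[1]
    n = state.xi.shape[0]
    S = config.phi_scale(k) + state.xi.T @ state.xi
    df = config.phi_df(k) + n
    Phi = invwishart.rvs(df=df, scale=S, random_state=rng)
    return np.atleast_2d(Phi)


def update_structural_params(
    state: SamplerState,
    spec: ModelSpec,
    C: np.ndarray,
    config: McmcConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Joint normal draw of (intercept, beta, gamma) given propensities.

    Regression of the outcome propensity on (1, covariates, factor scores)
    with residual variance fixed at 1 and N(0, v0) priors.
    """
    n = state.xi.shape[0]
    W = np.column_stack([np.ones(n), C, state.xi])
    prec = W.T @ W + np.eye(W.shape[1]) / config.prior_loc_var
    try:
        Lp = cholesky(prec, lower=True)
    except np.linalg.LinAlgError as exc:
        # identify near-collinear columns for the error message
        corr = np.corrcoef(W[:, 1:], rowvar=False)
        raise RuntimeFailure(
            "structural design matrix is rank deficient; "
            f"max absolute predictor correlation {np.abs(corr - np.eye(len(corr))).max():.4f}"
        ) from exc
    mean = cho_solve((Lp, True), W.T @ state.eta)
    draw = mean + solve_triangular(Lp, rng.standard_normal(len(mean)), lower=True, trans="T")
    nc = len(spec.covariates)
    return float(draw[0]), draw[1 : 1 + nc], draw[1 + nc :]


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained draws of every parameter, per chain.

    Leading array dimensions are (n_chains, n_retained).  ``xi_snapshots``
    keeps a thinned subsample of factor-score states (with the indices of
    the retained draws they belong to) for posterior predictive checks.
    """

    spec: ModelSpec
    config: McmcConfig
    mu: np.ndarray        # (C, T, p)
    lam: np.ndarray       # (C, T, p)
    psi: np.ndarray       # (C, T, p)
    Phi: np.ndarray       # (C, T, k, k)
    gamma: np.ndarray     # (C, T, k)
    beta: np.ndarray      # (C, T, n_cov)
    outcome_intercept: np.ndarray  # (C, T)
    xi_snapshots: np.ndarray       # (C, S, n, k)
    xi_snapshot_draws: np.ndarray  # (S,) retained-draw index of each snapshot
    standardization: Optional[dict] = None  # {col: (mean, sd)} applied by fit
    spec_hash: str = ""
    wall_seconds: float = 0.0

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_retained(self) -> int:
        return self.mu.shape[1]

    def parameter_chains(self) -> dict[str, np.ndarray]:
        """Per-chain draw matrix (C, T) for every free parameter, by name."""
        spec = self.spec
        out: dict[str, np.ndarray] = {}
        for j, ind in enumerate(spec.indicators):
            out[f"mu[{ind.name}]"] = self.mu[:, :, j]
        for j, ind in enumerate(spec.indicators):
            if not ind.is_reference:
                out[f"lam[{ind.name}]"] = self.lam[:, :, j]
        for j, ind in enumerate(spec.indicators):
            if ind.scale == CONTINUOUS:
                out[f"psi[{ind.name}]"] = self.psi[:, :, j]
        k = spec.n_factors
        for a in range(k):
            for b in range(a, k):
                out[f"Phi[{spec.factors[a]},{spec.factors[b]}]"] = self.Phi[:, :, a, b]
        for a, f in enumerate(spec.factors):
            out[f"gamma[{f}]"] = self.gamma[:, :, a]
        for c, cov in enumerate(spec.covariates):
            out[f"beta[{cov.name}]"] = self.beta[:, :, c]
        out["outcome_intercept"] = self.outcome_intercept
        return out

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one named parameter."""
        return self.parameter_chains()[name].reshape(-1)

    def draw_params(self, chain: int, t: int) -> ParameterSet:
        return ParameterSet(
            mu=self.mu[chain, t],
            lam=self.lam[chain, t],
            psi=self.psi[chain, t],
            Phi=self.Phi[chain, t],
            gamma=self.gamma[chain, t],
            beta=self.beta[chain, t],
            outcome_intercept=float(self.outcome_intercept[chain, t]),
        )

    def posterior_mean(self, name: str) -> float:
        return float(self.pooled(name).mean())


# ---------------------------------------------------------------------------
# Data preparation and the main loop
# ---------------------------------------------------------------------------


def _prepare_data(
    spec: ModelSpec, data: CohortTable, standardize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Optional[dict]]:
    """Validate and split the cohort into (Y indicators, C covariates, y outcome)."""
    data.validate()
    df = data.df
    na_cols = [c for c in df.columns if df[c].isna().any()]
    if na_cols:
        raise ValidationError(f"missing values in columns {na_cols}; complete cases required")

    Y = df[list(spec.indicator_names)].to_numpy(dtype=float).copy()
    C = df[list(spec.covariate_names)].to_numpy(dtype=float)
    y = df[spec.outcome].to_numpy(dtype=float)

    schema = None
    if standardize:
        schema = {}
        for j, ind in enumerate(spec.indicators):
            if ind.scale != CONTINUOUS:
                continue
            m, s = Y[:, j].mean(), Y[:, j].std(ddof=1)
            if s == 0:
                raise ValidationError(f"continuous indicator {ind.name!r} has zero variance")
            Y[:, j] = (Y[:, j] - m) / s
            schema[ind.name] = (float(m), float(s))
    return Y, C, y, schema


def _initial_state(
    spec: ModelSpec, Y: np.ndarray, C: np.ndarray, y: np.ndarray,
    rng: np.random.Generator,
) -> SamplerState:
    p_ind = spec.n_indicators
    k = spec.n_factors
    n = Y.shape[0]
    mu = np.zeros(p_ind)
    lam = np.empty(p_ind)
    psi = np.ones(p_ind)
    for j, ind in enumerate(spec.indicators):
        if ind.scale == CONTINUOUS:
            mu[j] = Y[:, j].mean()
            psi[j] = max(Y[:, j].var(ddof=1), 1e-3) / 2.0
        else:
            prev = np.clip(Y[:, j].mean(), 1e-3, 1 - 1e-3)
            mu[j] = ndtri(prev)
        # mild over-dispersion across chains for convergence diagnostics
        lam[j] = ind.loading_fixed if ind.is_reference else 0.5 + 0.2 * rng.standard_normal()
        mu[j] += 0.1 * rng.standard_normal()
    prev_out = np.clip(y.mean() if n else 0.5, 1e-3, 1 - 1e-3)
    params = ParameterSet(
        mu=mu,
        lam=lam,
        psi=psi,
        Phi=np.eye(k),
        gamma=0.1 * rng.standard_normal(k),
        beta=np.zeros(C.shape[1]),
        outcome_intercept=float(ndtri(prev_out)),
    )
    ystar = Y.copy()
    eta = np.zeros(n)
    return SamplerState(params=params, xi=np.zeros((n, k)), ystar=ystar, eta=eta)


def _run_chain(
    spec: ModelSpec,
    Y: np.ndarray,
    C: np.ndarray,
    y: np.ndarray,
    config: McmcConfig,
    chain: int,
    snapshot_draws: np.ndarray,
    store: dict[str, np.ndarray],
) -> None:
    rng = np.random.default_rng(config.chain_seed(chain))
    state = _initial_state(spec, Y, C, y, rng)
    p = state.params
    n = Y.shape[0]
    fidx = np.asarray(spec.indicator_factor_index())
    binary_j = [j for j, ind in enumerate(spec.indicators) if ind.scale == BINARY]

    t_retained = 0
    snap_set = set(int(s) for s in snapshot_draws)
    t0 = time.perf_counter()
    for it in range(config.n_iter):
        # 1. augmentation
        for j in binary_j:
            lin = p.mu[j] + p.lam[j] * state.xi[:, fidx[j]]
            state.ystar[:, j] = impute_binary_propensity(Y[:, j], lin, rng)
        lin_out = p.outcome_intercept + C @ p.beta + state.xi @ p.gamma
        state.eta = impute_binary_propensity(y, lin_out, rng)

        # 2..6. conjugate blocks, fixed order
        state.xi = update_factor_scores(state, spec, C, rng)
        p.mu, p.lam = update_measurement_params(state, spec, config, rng)
        p.psi = update_residual_variances(state, spec, config, rng)
        p.Phi = update_factor_covariance(state, config, rng)
        (p.outcome_intercept, p.beta, p.gamma) = update_structural_params(
            state, spec, C, config, rng
        )

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            t = t_retained
            store["mu"][chain, t] = p.mu
            store["lam"][chain, t] = p.lam
            store["psi"][chain, t] = p.psi
            store["Phi"][chain, t] = p.Phi
            store["gamma"][chain, t] = p.gamma
            store["beta"][chain, t] = p.beta
            store["outcome_intercept"][chain, t] = p.outcome_intercept
            if t in snap_set:
                s = int(np.searchsorted(snapshot_draws, t))
                store["xi"][chain, s] = state.xi
            t_retained += 1
        if (it + 1) % 100 == 0:
            logger.debug("chain %d: iteration %d/%d", chain, it + 1, config.n_iter)
    logger.info(
        "chain %d finished %d iterations in %.1f s (seed %d)",
        chain, config.n_iter, time.perf_counter() - t0, config.chain_seed(chain),
    )


def fit(
    spec: ModelSpec,
    data: CohortTable,
    config: McmcConfig = McmcConfig(),
    standardize: bool = True,
) -> PosteriorDraws:
    """Fit the model by Gibbs sampling and return the retained draws.

    ``standardize=True`` (default) z-scores continuous indicator columns
    before fitting and records the (mean, SD) pairs used; disable it when
    the input is already on a standardized scale (e.g. cohorts from
    :func:`pathsem.synthetic.simulate_cohort`, whose indicators are
    generated standardized — re-scoring would silently change the latent
    scale set by the reference indicators).  Deterministic given
    ``(spec, data, config)``.
    """
    require_valid(spec)
    config.validate(spec.n_factors)
    Y, C, y, schema = _prepare_data(spec, data, standardize)
    n = Y.shape[0]
    if n == 0:
        raise ValidationError("cannot fit on an empty cohort")

    T = config.n_retained()
    if T < 1:
        raise ValidationError("no retained draws: check n_iter / n_burnin / thin")
    p_ind, k, nc = spec.n_indicators, spec.n_factors, len(spec.covariates)
    n_snap = min(config.xi_snapshot_count, T)
    snapshot_draws = np.unique(np.linspace(0, T - 1, n_snap).astype(int))

    store = {
        "mu": np.empty((config.n_chains, T, p_ind)),
        "lam": np.empty((config.n_chains, T, p_ind)),
        "psi": np.empty((config.n_chains, T, p_ind)),
        "Phi": np.empty((config.n_chains, T, k, k)),
        "gamma": np.empty((config.n_chains, T, k)),
        "beta": np.empty((config.n_chains, T, nc)),
        "outcome_intercept": np.empty((config.n_chains, T)),
        "xi": np.empty((config.n_chains, len(snapshot_draws), n, k)),
    }
    t0 = time.perf_counter()
    for chain in range(config.n_chains):
        _run_chain(spec, Y, C, y, config, chain, snapshot_draws, store)

    return PosteriorDraws(
        spec=spec,
        config=config,
        mu=store["mu"],
        lam=store["lam"],
        psi=store["psi"],
        Phi=store["Phi"],
        gamma=store["gamma"],
        beta=store["beta"],
        outcome_intercept=store["outcome_intercept"],
        xi_snapshots=store["xi"],
        xi_snapshot_draws=snapshot_draws,
        standardization=schema,
        spec_hash=spec.spec_hash(),
        wall_seconds=time.perf_counter() - t0,
    )
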