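"""Convergence and model-fit diagnostics.

Three checks are reported: the Gelman–Rubin potential scale reduction
factor (PSRF) per parameter, the batch-means Monte Carlo standard error,
and a posterior predictive p-value (PPP) for overall model fit.  A PSRF
near 1 and small Monte Carlo errors indicate converged chains; a PPP near
0.5 indicates that replicated data generated from the posterior look like
the observed data under the chosen discrepancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ValidationError
from .gibbs import PosteriorDraws
from .model_spec import CONTINUOUS, ModelSpec
from .params import ParameterSet
from .synthetic import CohortTable

__all__ = [
    "gelman_rubin",
    "mc_error",
    "posterior_predictive_p",
    "DiagnosticsReport",
    "diagnose",
]

PSRF_FLAG_THRESHOLD = 1.1


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor of one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  With
    within-chain variance W (mean of per-chain sample variances) and
    between-chain variance B = n * var(chain means),

        PSRF = sqrt( ((n - 1)/n * W + B/n) / W ).

    This is the classic non-split statistic; ``split=True`` halves each
    chain first.
    """
    try:
        arr = np.asarray(chains, dtype=float)
    except ValueError as exc:  # ragged list of unequal-length chains
        raise ValidationError("chains must have equal lengths") from exc
    if arr.ndim != 2:
        raise ValidationError("chains must be a rectangular (m, n) array of equal lengths")
    if split:
        m, n = arr.shape
        half = n // 2
        arr = np.concatenate([arr[:, :half], arr[:, n - half:]], axis=0)
    m, n = arr.shape
    if m < 2:
        raise ValidationError("need at least 2 chains")
    if n < 2:
        raise ValidationError("need at least 2 draws per chain")
    W = arr.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValidationError("degenerate chains: within-chain variance is zero")
    B = n * arr.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def mc_error(draws: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of a posterior mean.

    The draw sequence is split into ``n_batches`` consecutive batches
    (trailing remainder discarded) and the SD of the batch means divided
    by sqrt(n_batches) is returned.
    """
    x = np.asarray(draws, dtype=float).ravel()
    batch = len(x) // n_batches
    if batch < 2:
        raise ValidationError(
            f"too few draws ({len(x)}) for {n_batches} batches of at least 2"
        )
    x = x[: batch * n_batches]
    means = x.reshape(n_batches, batch).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


# ---------------------------------------------------------------------------
# Posterior predictive check
# ---------------------------------------------------------------------------


def _default_discrepancy(
    Y: np.ndarray,
    C: np.ndarray,
    y_out: np.ndarray,
    xi: np.ndarray,
    params: ParameterSet,
    spec: ModelSpec,
    fidx: np.ndarray,
) -> float:
    """Standardized squared residuals (continuous) + squared Pearson
    residuals on the probit mean (binary indicators and outcome)."""
    # predicted probabilities are capped away from 0/1: a single cell with
    # p ~ 1e-6 would otherwise contribute an O(1/p) Pearson term and
    # dominate the whole sum
    cap = 1e-3
    total = 0.0
    for j, ind in enumerate(spec.indicators):
        lin = params.mu[j] + params.lam[j] * xi[:, fidx[j]]
        if ind.scale == CONTINUOUS:
            r = Y[:, j] - lin
            total += float(r @ r / params.psi[j])
        else:
            p = np.clip(ndtr(lin), cap, 1 - cap)
            total += float(np.sum((Y[:, j] - p) ** 2 / (p * (1 - p))))
    lin = params.outcome_intercept + C @ params.beta + xi @ params.gamma
    p = np.clip(ndtr(lin), cap, 1 - cap)
    total += float(np.sum((y_out - p) ** 2 / (p * (1 - p))))
    return total


def posterior_predictive_p(
    draws: PosteriorDraws,
    spec: ModelSpec,
    data: CohortTable,
    seed: int = 0,
    discrepancy: Optional[Callable] = None,
) -> float:
    """Posterior predictive p-value of the fitted model.

    For each stored factor-score snapshot t, a replicate data set is
    simulated from the model at the draw's parameters (and its factor
    scores), and the discrepancy of replicate and observed data compared:
    ppp = proportion of draws with D(y_rep) >= D(y_obs), ties counted 0.5.
    """
    if draws.n_retained < 1 or draws.xi_snapshots.shape[1] < 1:
        raise ValidationError("no retained draws available for the predictive check")
    if spec.spec_hash() != draws.spec_hash:
        raise ValidationError("draws were produced under a different model spec")
    data.validate()
    D = discrepancy or _default_discrepancy

    df = data.df
    Y = df[list(spec.indicator_names)].to_numpy(dtype=float).copy()
    C = df[list(spec.covariate_names)].to_numpy(dtype=float)
    y_out = df[spec.outcome].to_numpy(dtype=float)
    if draws.standardization:
        for j, ind in enumerate(spec.indicators):
            if ind.name in draws.standardization:
                m, s = draws.standardization[ind.name]
                Y[:, j] = (Y[:, j] - m) / s

    fidx = np.asarray(spec.indicator_factor_index())
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    exceed = 0.0
    n_eval = 0
    for chain in range(draws.n_chains):
        for s, t in enumerate(draws.xi_snapshot_draws):
            params = draws.draw_params(chain, int(t))
            xi = draws.xi_snapshots[chain, s]
            d_obs = D(Y, C, y_out, xi, params, spec, fidx)
            # replicate data at the same parameters and factor scores
            Yrep = np.empty_like(Y)
            for j, ind in enumerate(spec.indicators):
                lin = params.mu[j] + params.lam[j] * xi[:, fidx[j]]
                if ind.scale == CONTINUOUS:
                    Yrep[:, j] = lin + np.sqrt(params.psi[j]) * rng.standard_normal(n)
                else:
                    Yrep[:, j] = (lin + rng.standard_normal(n) > 0).astype(float)
            lin = params.outcome_intercept + C @ params.beta + xi @ params.gamma
            yrep_out = (lin + rng.standard_normal(n) > 0).astype(float)
            d_rep = D(Yrep, C, yrep_out, xi, params, spec, fidx)
            if d_rep > d_obs:
                exceed += 1.0
            elif d_rep == d_obs:
                exceed += 0.5
            n_eval += 1
    return exceed / n_eval


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence table plus model-level fit summary."""

    table: pd.DataFrame          # columns: parameter, psrf, mcse, ess
    ppp: Optional[float]
    flagged: list[str]           # parameters with PSRF above threshold

    @property
    def max_psrf(self) -> float:
        return float(self.table["psrf"].max())

    def to_json(self) -> str:
        return json.dumps(
            {
                "ppp": self.ppp,
                "max_psrf": self.max_psrf,
                "flagged": self.flagged,
                "parameters": self.table.to_dict(orient="records"),
            },
            indent=2,
        )


def diagnose(
    draws: PosteriorDraws,
    data: Optional[CohortTable] = None,
    seed: int = 0,
    psrf_threshold: float = PSRF_FLAG_THRESHOLD,
) -> DiagnosticsReport:
    """Compute PSRF, Monte Carlo error and effective sample size for every
    free parameter, plus the posterior predictive p-value when the fitted
    cohort is supplied."""
    import arviz as az

    rows = []
    flagged = []
    for name, chains in draws.parameter_chains().items():
        psrf = np.nan
        if chains.shape[0] >= 2 and chains.var(axis=1, ddof=1).mean() > 0:
            psrf = gelman_rubin(chains)
            if psrf > psrf_threshold:
                flagged.append(name)
        pooled = chains.reshape(-1)
        mcse = mc_error(pooled) if len(pooled) >= 40 else np.nan
        ess = float(az.ess(az.convert_to_dataset(chains))["x"].values.item())
        rows.append({"parameter": name, "psrf": psrf, "mcse": mcse, "ess": ess})
    table = pd.DataFrame(rows)
    ppp = None
    if data is not None:
        ppp = posterior_predictive_p(draws, draws.spec, data, seed=seed)
    return DiagnosticsReport(table=table, ppp=ppp, flagged=flagged)
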