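"""Parameter containers shared by the simulator and the Gibbs sampler.

A :class:`ParameterSet` is one complete point in parameter space: it is used
both as the generating truth of a synthetic cohort and as a single MCMC
state.  :class:`GenerativeParams` adds the covariate marginals the simulator
needs (age distribution, sex and family-history prevalences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model_spec import BINARY, CONTINUOUS, ModelSpec


@dataclass
class ParameterSet:
    """One full set of model parameters.

    Attributes
    ----------
    mu : (n_indicators,) intercept of each indicator.
    lam : (n_indicators,) loading of each indicator on its factor
        (fixed entries hold their fixed value, 1.0 for references).
    psi : (n_indicators,) residual variance; exactly 1.0 for binary
        indicators (probit identification), > 0 for continuous ones.
    Phi : (k, k) symmetric positive-definite latent covariance.
    gamma : (k,) structural coefficients of the factors on the outcome
        propensity.
    beta : (n_covariates,) covariate coefficients on the outcome propensity.
    outcome_intercept : scalar intercept of the outcome propensity.
    """

    mu: np.ndarray
    lam: np.ndarray
    psi: np.ndarray
    Phi: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    outcome_intercept: float

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            mu=self.mu.copy(),
            lam=self.lam.copy(),
            psi=self.psi.copy(),
            Phi=self.Phi.copy(),
            gamma=self.gamma.copy(),
            beta=self.beta.copy(),
            outcome_intercept=float(self.outcome_intercept),
        )

    def validate(self, spec: ModelSpec) -> None:
        p, k, c = spec.n_indicators, spec.n_factors, len(spec.covariates)
        shapes = {
            "mu": (self.mu, (p,)),
            "lam": (self.lam, (p,)),
            "psi": (self.psi, (p,)),
            "Phi": (self.Phi, (k, k)),
            "gamma": (self.gamma, (k,)),
            "beta": (self.beta, (c,)),
        }
        for name, (arr, want) in shapes.items():
            if np.shape(arr) != want:
                raise ValidationError(f"{name} has shape {np.shape(arr)}, expected {want}")
        for j, ind in enumerate(spec.indicators):
            if ind.loading_fixed is not None and self.lam[j] != ind.loading_fixed:
                raise ValidationError(
                    f"loading of reference indicator {ind.name!r} is {self.lam[j]}, "
                    f"must equal its fixed value {ind.loading_fixed}"
                )
            if ind.scale == BINARY and self.psi[j] != 1.0:
                raise ValidationError(
                    f"residual variance of binary indicator {ind.name!r} must be fixed at 1"
                )
        if np.any(self.psi <= 0):
            raise ValidationError("psi must be strictly positive")
        if not np.allclose(self.Phi, self.Phi.T):
            raise ValidationError("Phi is not symmetric")
        if np.linalg.eigvalsh(self.Phi).min() <= 0:
            raise ValidationError("Phi is not positive definite")

    # ---- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "lam": self.lam.tolist(),
            "psi": self.psi.tolist(),
            "Phi": self.Phi.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "outcome_intercept": float(self.outcome_intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            lam=np.asarray(d["lam"], dtype=float),
            psi=np.asarray(d["psi"], dtype=float),
            Phi=np.asarray(d["Phi"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            outcome_intercept=float(d["outcome_intercept"]),
        )


@dataclass
class GenerativeParams(ParameterSet):
    """ParameterSet plus covariate marginals used only when simulating.

    Age is drawn from a normal distribution left-truncated at ``age_min``
    (the cohort's inclusion threshold); sex and family history are
    Bernoulli.  Covariates are generated independently of the latent
    factors: the structural model conditions on them without modelling
    their joint distribution.
    """

    age_mean: float = 48.4
    age_sd: float = 10.0
    age_min: float = 35.0
    sex_prevalence: float = 0.51
    family_history_prevalence: float = 0.06

    def validate(self, spec: ModelSpec) -> None:
        super().validate(spec)
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be > 0")
        for name in ("sex_prevalence", "family_history_prevalence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(
            age_mean=self.age_mean,
            age_sd=self.age_sd,
            age_min=self.age_min,
            sex_prevalence=self.sex_prevalence,
            family_history_prevalence=self.family_history_prevalence,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        base = ParameterSet.from_dict(d)
        return cls(
            **base.__dict__,
            age_mean=float(d.get("age_mean", 48.4)),
            age_sd=float(d.get("age_sd", 10.0)),
            age_min=float(d.get("age_min", 35.0)),
            sex_prevalence=float(d.get("sex_prevalence", 0.51)),
            family_history_prevalence=float(d.get("family_history_prevalence", 0.06)),
        )


# ---------------------------------------------------------------------------
# Canonical flat parameter naming (shared by diagnostics / effects / recovery)
# ---------------------------------------------------------------------------


def free_parameter_names(spec: ModelSpec) -> list[str]:
    """Ordered names of every free parameter of the model.

    Order: mu, free lam, psi (continuous), Phi upper triangle (row-major,
    diagonal included), gamma, beta, outcome intercept.  The length equals
    :func:`pathsem.model_spec.count_free_parameters`.
    """
    names: list[str] = [f"mu[{ind.name}]" for ind in spec.indicators]
    names += [f"lam[{ind.name}]" for ind in spec.indicators if not ind.is_reference]
    names += [f"psi[{ind.name}]" for ind in spec.indicators if ind.scale == CONTINUOUS]
    k = spec.n_factors
    for a in range(k):
        for b in range(a, k):
            names.append(f"Phi[{spec.factors[a]},{spec.factors[b]}]")
    names += [f"gamma[{f}]" for f in spec.factors]
    names += [f"beta[{c.name}]" for c in spec.covariates]
    names.append("outcome_intercept")
    return names


def flatten_free(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Free-parameter values of ``params`` in :func:`free_parameter_names` order."""
    vals: list[float] = list(params.mu)
    vals += [params.lam[j] for j, ind in enumerate(spec.indicators) if not ind.is_reference]
    vals += [params.psi[j] for j, ind in enumerate(spec.indicators) if ind.scale == CONTINUOUS]
    k = spec.n_factors
    for a in range(k):
        for b in range(a, k):
            vals.append(params.Phi[a, b])
    vals += list(params.gamma)
    vals += list(params.beta)
    vals.append(params.outcome_intercept)
    return np.asarray(vals, dtype=float)
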