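"""Declarative description of the structural equation model.

The model links six correlated latent constructs (lipids, anthropometric,
risky behaviour, comorbidities, quality of life, healthy lifestyle) to a
binary cardiovascular outcome.  Each construct is measured by several
observed indicators — a mix of continuous scores/lab values and binary
status variables — with one reference indicator per construct whose
loading is fixed at 1 to set the latent scale.  Three observed covariates
(age, sex, family history) enter the outcome equation directly.

Everything downstream (simulation, Gibbs fitting, diagnostics, effect
tables) consumes a :class:`ModelSpec`; this module is the single source of
truth for variable names, scales and identification constraints.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ValidationError

CONTINUOUS = "continuous"
BINARY = "binary"

OUTCOME_LABELS = ("total_cvd", "stroke", "acs", "fatal_cvd")


@dataclass(frozen=True)
class IndicatorDef:
    """One observed indicator of a latent construct.

    ``loading_fixed`` is 1.0 for the reference indicator of the construct
    and ``None`` for indicators whose loading is estimated.
    """

    name: str
    factor: str
    scale: str = CONTINUOUS
    loading_fixed: Optional[float] = None

    @property
    def is_reference(self) -> bool:
        return self.loading_fixed is not None


@dataclass(frozen=True)
class CovariateDef:
    name: str
    scale: str = CONTINUOUS


@dataclass(frozen=True)
class ModelSpec:
    """Complete measurement + structural layout of the model.

    The default instance (see :func:`build_default_spec`) has 6 factors,
    18 indicators, 3 covariates and 1 binary outcome — 21 measured
    predictor variables plus the outcome.
    """

    factors: tuple[str, ...]
    indicators: tuple[IndicatorDef, ...]
    covariates: tuple[CovariateDef, ...]
    outcome: str
    outcome_label: str

    # ---- derived layout helpers -------------------------------------

    @property
    def indicator_names(self) -> tuple[str, ...]:
        return tuple(ind.name for ind in self.indicators)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def column_order(self) -> tuple[str, ...]:
        """Canonical cohort-table column order: covariates, indicators, outcome."""
        return self.covariate_names + self.indicator_names + (self.outcome,)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def factor_index(self, name: str) -> int:
        return self.factors.index(name)

    def indicator_factor_index(self) -> list[int]:
        """Factor index of each indicator, in indicator order."""
        return [self.factors.index(ind.factor) for ind in self.indicators]

    def continuous_indicator_mask(self) -> list[bool]:
        return [ind.scale == CONTINUOUS for ind in self.indicators]

    def binary_columns(self) -> tuple[str, ...]:
        """All binary columns in the cohort table, outcome included."""
        cols = [c.name for c in self.covariates if c.scale == BINARY]
        cols += [i.name for i in self.indicators if i.scale == BINARY]
        cols.append(self.outcome)
        return tuple(cols)

    def indicators_of(self, factor: str) -> list[IndicatorDef]:
        return [ind for ind in self.indicators if ind.factor == factor]

    # ---- serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "factors": list(self.factors),
            "indicators": [
                {
                    "name": i.name,
                    "factor": i.factor,
                    "scale": i.scale,
                    **(
                        {"loading_fixed": float(i.loading_fixed)}
                        if i.loading_fixed is not None
                        else {}
                    ),
                }
                for i in self.indicators
            ],
            "covariates": [{"name": c.name, "scale": c.scale} for c in self.covariates],
            "outcome": self.outcome,
            "outcome_label": self.outcome_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        try:
            return cls(
                factors=tuple(d["factors"]),
                indicators=tuple(
                    IndicatorDef(
                        name=i["name"],
                        factor=i["factor"],
                        scale=i.get("scale", CONTINUOUS),
                        loading_fixed=i.get("loading_fixed"),
                    )
                    for i in d["indicators"]
                ),
                covariates=tuple(
                    CovariateDef(name=c["name"], scale=c.get("scale", CONTINUOUS))
                    for c in d["covariates"]
                ),
                outcome=d["outcome"],
                outcome_label=d["outcome_label"],
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed spec mapping: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def spec_hash(self) -> str:
        """Stable content hash used to tie draws/truth manifests to a spec."""
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Default (cohort-study) specification
# ---------------------------------------------------------------------------

# factor -> [(indicator, scale, reference?)]; first entry of each factor is
# the reference indicator (loading fixed at 1).
_DEFAULT_LAYOUT: dict[str, list[tuple[str, str]]] = {
    "lipids": [("hdl", CONTINUOUS), ("ldl", CONTINUOUS), ("tg", CONTINUOUS), ("tcho", CONTINUOUS)],
    "anthropometric": [("hc", CONTINUOUS), ("wc", CONTINUOUS), ("bmi", CONTINUOUS)],
    "risky_behaviour": [
        ("smoking", BINARY),
        ("depression_anxiety", CONTINUOUS),
        ("unhealthy_diet", CONTINUOUS),
    ],
    "comorbidities": [("dm", BINARY), ("bp", BINARY)],
    "quality_of_life": [
        ("qol_environmental", CONTINUOUS),
        ("qol_social", CONTINUOUS),
        ("qol_mental", CONTINUOUS),
        ("qol_physical", CONTINUOUS),
    ],
    "healthy_lifestyle": [("physical_activity", CONTINUOUS), ("healthy_diet", CONTINUOUS)],
}

_DEFAULT_COVARIATES = (
    CovariateDef("age", CONTINUOUS),
    CovariateDef("sex", BINARY),
    CovariateDef("family_history", BINARY),
)


def build_default_spec(outcome_label: str = "total_cvd") -> ModelSpec:
    """Return the default cohort specification for one of the four outcomes.

    Parameters
    ----------
    outcome_label
        One of ``total_cvd``, ``stroke``, ``acs``, ``fatal_cvd``.  The
        measurement structure is identical across outcomes; only the
        outcome column name changes.
    """
    if outcome_label not in OUTCOME_LABELS:
        raise ValidationError(
            f"unknown outcome label {outcome_label!r}; valid labels: {list(OUTCOME_LABELS)}"
        )
    indicators = []
    for factor, inds in _DEFAULT_LAYOUT.items():
        for pos, (name, scale) in enumerate(inds):
            indicators.append(
                IndicatorDef(
                    name=name,
                    factor=factor,
                    scale=scale,
                    loading_fixed=1.0 if pos == 0 else None,
                )
            )
    return ModelSpec(
        factors=tuple(_DEFAULT_LAYOUT),
        indicators=tuple(indicators),
        covariates=_DEFAULT_COVARIATES,
        outcome=outcome_label,
        outcome_label=outcome_label,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Collected structural violations; empty iff the spec is usable."""

    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when there are problems
        return bool(self.violations)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_spec(spec: ModelSpec) -> ValidationReport:
    """Check a spec for structural problems; never raises."""
    report = ValidationReport()
    v = report.violations

    names = (
        list(spec.covariate_names) + list(spec.indicator_names) + [spec.outcome]
    )
    seen: set[str] = set()
    for name in names:
        if name in seen:
            v.append(f"duplicate variable name: {name!r}")
        seen.add(name)

    if len(set(spec.factors)) != len(spec.factors):
        v.append("duplicate factor identifiers")

    for ind in spec.indicators:
        if ind.factor not in spec.factors:
            v.append(f"indicator {ind.name!r} assigned to unknown factor {ind.factor!r}")
        if ind.scale not in (CONTINUOUS, BINARY):
            v.append(f"indicator {ind.name!r} has invalid scale {ind.scale!r}")
        if ind.loading_fixed is not None and ind.loading_fixed != 1.0:
            v.append(
                f"indicator {ind.name!r} has fixed loading {ind.loading_fixed}; only 1.0 is supported"
            )

    for factor in spec.factors:
        inds = spec.indicators_of(factor)
        if not inds:
            v.append(f"factor {factor!r} has no indicators")
            continue
        n_ref = sum(ind.is_reference for ind in inds)
        if n_ref == 0:
            v.append(f"factor {factor!r} has no reference indicator (fixed loading)")
        elif n_ref > 1:
            v.append(f"factor {factor!r} has multiple reference indicators")

    for cov in spec.covariates:
        if cov.scale not in (CONTINUOUS, BINARY):
            v.append(f"covariate {cov.name!r} has invalid scale {cov.scale!r}")

    return report


def require_valid(spec: ModelSpec) -> None:
    report = validate_spec(spec)
    if report:
        raise ValidationError("invalid model spec: " + "; ".join(report.violations))


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free parameters of the model defined by ``spec``.

    Intercepts (one per indicator) + free loadings + residual variances of
    continuous indicators + distinct latent covariance entries + structural
    coefficients of factors and covariates + the outcome intercept.
    """
    require_valid(spec)
    k = spec.n_factors
    n_ind = spec.n_indicators
    n_free_loadings = sum(1 for ind in spec.indicators if not ind.is_reference)
    n_psi = sum(1 for ind in spec.indicators if ind.scale == CONTINUOUS)
    n_phi = k * (k + 1) // 2
    return n_ind + n_free_loadings + n_psi + n_phi + k + len(spec.covariates) + 1
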