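"""Cohort file I/O, standardization, draws persistence, and the pipeline runner.

CSV dialect is fixed (comma separator, '.' decimal, UTF-8, header row
required) for bit-exact reproducibility.  All randomness in
:func:`run_pipeline` flows from one top-level seed; every stage logs the
derived seed it used and the provenance manifest records them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import RuntimeFailure, ValidationError
from .gibbs import McmcConfig, PosteriorDraws, fit
from .model_spec import CONTINUOUS, ModelSpec, build_default_spec, require_valid
from .params import GenerativeParams
from .synthetic import (
    OUTCOME_PREVALENCE,
    CohortTable,
    CohortTruth,
    calibrate_outcome_intercept,
    default_true_params,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSchema",
    "read_cohort_csv",
    "write_cohort_csv",
    "standardize",
    "destandardize",
    "write_truth_manifest",
    "read_truth_manifest",
    "save_draws",
    "load_draws",
    "run_pipeline",
]


@dataclass(frozen=True)
class ColumnSchema:
    """Role/scale metadata of one cohort column, with any standardization
    applied to it (mean, sd recorded iff the column was z-scored)."""

    name: str
    role: str    # covariate | indicator | outcome
    scale: str   # continuous | binary
    standardized: bool = False
    mean: Optional[float] = None
    sd: Optional[float] = None


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------


def read_cohort_csv(path: str | Path, spec: ModelSpec) -> CohortTable:
    """Read a complete-case cohort; any missing cell is a hard error."""
    require_valid(spec)
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path, sep=",", decimal=".", encoding="utf-8")
    except Exception as exc:
        raise ValidationError(f"could not parse {path}: {exc}") from exc

    missing_cols = [c for c in spec.column_order if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"required columns absent from {path.name}: {missing_cols}")
    df = df[list(spec.column_order)]

    bad_cells = [
        (int(i), c) for c in df.columns for i in df.index[df[c].isna()]
    ]
    if bad_cells:
        raise ValidationError(
            f"missing values at (row, column): {bad_cells[:20]}"
            + ("..." if len(bad_cells) > 20 else "")
        )
    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValidationError(f"non-numeric values in column {c!r}")
    table = CohortTable(df=df.astype(float), spec=spec)
    table.validate()
    logger.info("read cohort %s: %d rows, %d columns", path.name, len(df), df.shape[1])
    return table


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False, encoding="utf-8")


def standardize(table: CohortTable, spec: ModelSpec) -> tuple[CohortTable, list[ColumnSchema]]:
    """Z-score continuous indicator columns; covariates and binaries untouched.

    Returns the transformed table and the full column schema (with the
    (mean, SD) pairs needed for exact back-transformation).
    """
    if table.n < 2:
        raise ValidationError("need at least 2 rows to standardize")
    df = table.df.copy()
    schema: list[ColumnSchema] = []
    roles = (
        [("covariate", c.name, c.scale) for c in spec.covariates]
        + [("indicator", i.name, i.scale) for i in spec.indicators]
        + [("outcome", spec.outcome, "binary")]
    )
    for role, name, scale in roles:
        if role == "indicator" and scale == CONTINUOUS:
            m = float(df[name].mean())
            s = float(df[name].std(ddof=1))
            if s == 0:
                raise ValidationError(f"zero-variance continuous column: {name!r}")
            df[name] = (df[name] - m) / s
            schema.append(ColumnSchema(name, role, scale, True, m, s))
        else:
            schema.append(ColumnSchema(name, role, scale))
    return CohortTable(df=df, spec=spec, truth=table.truth), schema


def destandardize(table: CohortTable, schema: list[ColumnSchema]) -> CohortTable:
    """Invert :func:`standardize` using the recorded (mean, SD) pairs."""
    df = table.df.copy()
    for col in schema:
        if col.standardized:
            df[col.name] = df[col.name] * col.sd + col.mean
    return CohortTable(df=df, spec=table.spec, truth=table.truth)


# ---------------------------------------------------------------------------
# Truth manifest / draws persistence
# ---------------------------------------------------------------------------


def write_truth_manifest(truth: CohortTruth, path: str | Path) -> None:
    doc = {
        "spec_hash": truth.spec_hash,
        "seed": truth.seed,
        "params": truth.params.to_dict(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_truth_manifest(path: str | Path) -> CohortTruth:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return CohortTruth(
        params=GenerativeParams.from_dict(doc["params"]),
        xi=np.empty((0, 0)),
        seed=doc.get("seed"),
        spec_hash=doc.get("spec_hash"),
    )


def save_draws(draws: PosteriorDraws, out_dir: str | Path) -> None:
    """Persist draws as a columnar .npz plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "draws.npz",
        mu=draws.mu, lam=draws.lam, psi=draws.psi, Phi=draws.Phi,
        gamma=draws.gamma, beta=draws.beta,
        outcome_intercept=draws.outcome_intercept,
        xi_snapshots=draws.xi_snapshots,
        xi_snapshot_draws=draws.xi_snapshot_draws,
    )
    manifest = {
        "spec": draws.spec.to_dict(),
        "spec_hash": draws.spec_hash,
        "config": {
            "n_chains": draws.config.n_chains,
            "n_iter": draws.config.n_iter,
            "n_burnin": draws.config.n_burnin,
            "thin": draws.config.thin,
            "seed": draws.config.seed,
            "prior_loc_var": draws.config.prior_loc_var,
            "prior_psi_shape": draws.config.prior_psi_shape,
            "prior_psi_rate": draws.config.prior_psi_rate,
        },
        "standardization": draws.standardization,
        "wall_seconds": draws.wall_seconds,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def load_draws(in_dir: str | Path) -> PosteriorDraws:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text(encoding="utf-8"))
    spec = ModelSpec.from_dict(manifest["spec"])
    cfg = McmcConfig(**manifest["config"])
    arrays = np.load(src / "draws.npz")
    std = manifest.get("standardization")
    if std is not None:
        std = {k: tuple(v) for k, v in std.items()}
    return PosteriorDraws(
        spec=spec,
        config=cfg,
        mu=arrays["mu"], lam=arrays["lam"], psi=arrays["psi"], Phi=arrays["Phi"],
        gamma=arrays["gamma"], beta=arrays["beta"],
        outcome_intercept=arrays["outcome_intercept"],
        xi_snapshots=arrays["xi_snapshots"],
        xi_snapshot_draws=arrays["xi_snapshot_draws"],
        standardization=std,
        spec_hash=manifest["spec_hash"],
        wall_seconds=manifest.get("wall_seconds", 0.0),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "fit", "diagnose", "effects")


def run_pipeline(config: dict) -> dict:
    """Execute the requested pipeline stages in order.

    ``config`` keys: ``out_dir`` (required), ``seed``, ``outcome_label``,
    ``stages`` (subset of simulate/fit/diagnose/effects), ``data`` (cohort
    CSV path, used when ``simulate`` is not requested), ``simulate``
    (``n``, ``prevalence``), ``fit`` (``chains``, ``iter``, ``burnin``,
    ``thin``, ``standardize``), ``effects`` (``correlation``).

    Stage outputs are persisted under ``out_dir``; a provenance manifest
    records seeds, the spec hash and the package version.  A stage failure
    halts the run, leaves partial outputs in place, and writes a FAILED
    marker naming the stage.
    """
    out_dir = Path(config.get("out_dir", "pathsem_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", _STAGES))
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}; valid: {list(_STAGES)}")
    needs_fit = [s for s in ("diagnose", "effects") if s in stages]
    if needs_fit and "fit" not in stages:
        raise ValidationError(
            f"stages {needs_fit} require 'fit' in the same run (dependency order)"
        )
    if "fit" in stages and "simulate" not in stages and "data" not in config:
        raise ValidationError("'fit' needs either a 'simulate' stage or a 'data' path")

    spec = build_default_spec(config.get("outcome_label", "total_cvd"))
    bundle: dict = {"out_dir": str(out_dir)}
    manifest = {
        "seed": seed,
        "stages": stages,
        "spec_hash": spec.spec_hash(),
        "version": __version__,
        "derived_seeds": {},
    }
    current_stage = None
    try:
        cohort = None
        truth = None
        if "simulate" in stages:
            current_stage = "simulate"
            sim_cfg = config.get("simulate", {})
            n = int(sim_cfg.get("n", 3161))
            prevalence = float(
                sim_cfg.get("prevalence", OUTCOME_PREVALENCE[spec.outcome_label])
            )
            sim_seed = seed
            manifest["derived_seeds"]["simulate"] = sim_seed
            logger.info("stage simulate: n=%d seed=%d", n, sim_seed)
            params = default_true_params(spec)
            params = calibrate_outcome_intercept(
                spec, params, prevalence, seed=sim_seed + 500_000
            )
            cohort = simulate_cohort(spec, params, n, seed=sim_seed)
            truth = cohort.truth
            write_cohort_csv(cohort, out_dir / "cohort.csv")
            write_truth_manifest(truth, out_dir / "truth.yaml")
            bundle["cohort"] = cohort
        elif "data" in config:
            cohort = read_cohort_csv(config["data"], spec)
            bundle["cohort"] = cohort

        draws = None
        if "fit" in stages:
            current_stage = "fit"
            fit_cfg = config.get("fit", {})
            mcmc = McmcConfig(
                n_chains=int(fit_cfg.get("chains", 2)),
                n_iter=int(fit_cfg.get("iter", 6000)),
                n_burnin=int(fit_cfg.get("burnin", 1000)),
                thin=int(fit_cfg.get("thin", 1)),
                seed=seed + 1_000,
            )
            manifest["derived_seeds"]["fit"] = mcmc.seed
            logger.info("stage fit: %d chains x %d iterations", mcmc.n_chains, mcmc.n_iter)
            standardize_flag = bool(fit_cfg.get("standardize", "simulate" not in stages))
            draws = fit(spec, cohort, mcmc, standardize=standardize_flag)
            save_draws(draws, out_dir / "draws")
            bundle["draws"] = draws

        if "diagnose" in stages:
            current_stage = "diagnose"
            from .diagnostics import diagnose

            diag_seed = seed + 2_000
            manifest["derived_seeds"]["diagnose"] = diag_seed
            report = diagnose(draws, data=cohort, seed=diag_seed)
            (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")
            bundle["diagnostics"] = report

        if "effects" in stages:
            current_stage = "effects"
            from .effects import (
                recovery_report,
                summarize_direct_effects,
                summarize_latent_covariances,
            )

            eff_cfg = config.get("effects", {})
            direct = summarize_direct_effects(draws, spec)
            covs = summarize_latent_covariances(
                draws, spec, as_correlation=bool(eff_cfg.get("correlation", False))
            )
            table = pd.concat([direct, covs], ignore_index=True)
            table.to_csv(out_dir / "effects.csv", index=False, float_format="%.6f")
            bundle["effects"] = table
            if truth is not None:
                rec = recovery_report(draws, truth)
                rec.table.to_csv(out_dir / "recovery.csv", index=False, float_format="%.6f")
                manifest["coverage"] = rec.coverage
                bundle["recovery"] = rec
    except Exception as exc:
        (out_dir / "FAILED").write_text(
            f"stage {current_stage!r} failed: {exc}\n", encoding="utf-8"
        )
        raise RuntimeFailure(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    bundle["manifest"] = manifest
    return bundle
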