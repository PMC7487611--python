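"""Convergence and fit diagnostics for the fitted model.

Reports the Gelman-Rubin statistic (PSRF), batch-means Monte Carlo error
and effective sample size per free parameter, and the posterior
predictive p-value of the fitted model on the cohort it was fitted to.
"""

import argparse
from pathlib import Path

from pathsem import build_default_spec
from pathsem.diagnostics import diagnose
from pathsem.io import load_draws, read_cohort_csv

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outcome", default="total_cvd")
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

spec = build_default_spec(args.outcome)
draws = load_draws(args.results / f"draws_{spec.outcome_label}")
cohort = read_cohort_csv(args.results / f"cohort_{spec.outcome_label}.csv", spec)

report = diagnose(draws, data=cohort, seed=args.seed + 2_000)
print(f"max PSRF over {len(report.table)} free parameters: {report.max_psrf:.4f}")
print(f"parameters flagged (PSRF > 1.1): {report.flagged or 'none'}")
print(f"median MC error: {report.table['mcse'].median():.5f}")
print(f"posterior predictive p-value: {report.ppp:.3f}")

out = args.results / f"diagnostics_{spec.outcome_label}.json"
out.write_text(report.to_json(), encoding="utf-8")
print(f"wrote {out}")
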