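import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pathsem import (  # noqa: E402
    McmcConfig,
    build_default_spec,
    calibrate_outcome_intercept,
    default_true_params,
    simulate_cohort,
    OUTCOME_PREVALENCE,
)


@pytest.fixture(scope="session")
def spec():
    return build_default_spec("total_cvd")


@pytest.fixture(scope="session")
def true_params(spec):
    params = default_true_params(spec)
    return calibrate_outcome_intercept(
        spec, params, OUTCOME_PREVALENCE["total_cvd"], seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(spec, true_params):
    """A cohort small enough for quick fits in unit tests."""
    return simulate_cohort(spec, true_params, n=400, seed=11)


@pytest.fixture(scope="session")
def small_draws(spec, small_cohort):
    """A quick reference fit reused across diagnostics/effects tests."""
    from pathsem import fit

    cfg = McmcConfig(n_chains=2, n_iter=800, n_burnin=300, seed=5)
    return fit(spec, small_cohort, cfg, standardize=False)
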