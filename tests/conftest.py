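import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a male-only direct PRS effect on the outcome."""
    from prstrata import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_individuals=2_000,
        n_variants=100,
        effect_c_prime=(0.25, 0.0),
        seed=99,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mediated_cohort():
    """Cohort with a male-only mediated path (a male-specific, b shared)."""
    from prstrata import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_individuals=4_000,
        n_variants=100,
        effect_a=(0.4, 0.0),
        effect_b=(0.5, 0.5),
        effect_c_prime=(-0.1, -0.1),
        seed=7,
    )
    return simulate_cohort(cfg)
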