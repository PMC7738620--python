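import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orthohrv.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale records-only cohort (10 athletes, 28-day calendar)."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def rr_cohort():
    """Tiny cohort with raw RR tachograms for end-to-end checks."""
    config = SimulationConfig(
        seed=7,
        n_athletes=2,
        n_stages=3,
        n_baseline=1,
        rest_after_stages=(),
        n_post=0,
        stage_km_mean=80.0,
        stage_km_sd=10.0,
    )
    return simulate_cohort(config, include_rr=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
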