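import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hba1c_mr import SimulationConfig, default_panel, simulate_cohort

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort_small():
    """Default-condition cohort at modest n for structural checks."""
    cfg = SimulationConfig(n_individuals=1500, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_large():
    """n = 100,000 cohort for law-of-large-numbers checks."""
    cfg = SimulationConfig(n_individuals=100_000, seed=11)
    return simulate_cohort(cfg)
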