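import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitcounts as gc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> gc.SimConfig:
    """A 6-participant configuration for fast end-to-end runs."""
    return gc.SimConfig(n_participants=6, seed=424242)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> "object":
    """Count-level cohort shared by read-only tests."""
    return gc.generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220527)
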