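import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from boardmap import build_grid, simulate_null_single

settings.register_profile(
    "boardmap",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("boardmap")


@pytest.fixture(scope="session")
def grid():
    """The study's stimulus layout: 6x6 grid, 3.3 cm spacing, 23 cm board."""
    return build_grid()


@pytest.fixture(scope="session")
def null_10k(grid):
    """A 10,000-simulation single-participant null at 8 reps/location."""
    return simulate_null_single(grid, reps_per_location=8, n_sims=10_000, seed=20240501)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
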