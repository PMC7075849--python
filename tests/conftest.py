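import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from weaksup.simulate import (  # noqa: E402
    SimConfig,
    correlated_block_preset,
    simulate_correlated,
    simulate_independent,
)


@pytest.fixture(scope="session")
def independent_sim():
    """Mid-size independent simulation with heterogeneous accuracies."""
    config = SimConfig(
        m=5000, n=6, accuracies=np.linspace(0.6, 0.9, 6), propensities=0.5, seed=1
    )
    return simulate_independent(config)


@pytest.fixture(scope="session")
def correlated_block_sim():
    """The pathological correlated-block configuration at full size."""
    return simulate_correlated(correlated_block_preset(m=10_000, seed=1))


@pytest.fixture(scope="session")
def random_vote_matrix():
    rng = np.random.default_rng(42)
    return rng.integers(-1, 2, size=(40, 5)).astype(np.int8)
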