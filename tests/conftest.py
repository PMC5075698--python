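import numpy as np
import pytest

from jointcox import SimScenario, get_scenario, simulate_dataset


@pytest.fixture(scope="session")
def set1_scenario():
    return get_scenario(1, seed=123)


@pytest.fixture(scope="session")
def set1_dataset(set1_scenario):
    return simulate_dataset(set1_scenario, 0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-subject replicate for quadrature and likelihood fixtures."""
    scenario = SimScenario(n_per_group=10, seed=99, set_id=1)
    return simulate_dataset(scenario, 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
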