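import numpy as np
import pytest

from megscreen.simulate import SimulationConfig, generate_cross_sectional, generate_longitudinal


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=60, n_cases=10, n_controls=10, seed=11)


@pytest.fixture(scope="session")
def cross_dataset(small_config):
    return generate_cross_sectional(small_config)


@pytest.fixture(scope="session")
def long_dataset(small_config):
    return generate_longitudinal(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
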