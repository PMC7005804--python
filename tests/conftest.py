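import numpy as np
import pytest

from methnet.divergence import call_dmps
from methnet.synthetic_data import SimulationConfig, simulate_methylomes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_data(small_config):
    return simulate_methylomes(small_config, np.random.default_rng(small_config.seed))


@pytest.fixture(scope="session")
def dmp_set(sim_data):
    reference = [s for s in sim_data.samples if s.group == "reference"]
    others = [s for s in sim_data.samples if s.group != "reference"]
    return call_dmps(others, reference, alpha=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
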