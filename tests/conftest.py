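import numpy as np
import pytest

from cngckit.simulate import SimulationConfig


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """One seeded study-condition config shared by the synthetic tests."""
    return SimulationConfig(seed=20170)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
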