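import numpy as np
import pytest

from regengrn.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_bundle():
    """One fully simulated small dataset shared across the suite."""
    config = SimulationConfig.small(seed=5)
    return config, simulate_all(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
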