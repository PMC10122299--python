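import numpy as np
import pytest

from graftgxe.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """Pocket-sized study: 300 genes, 2 blocks x 1 vine (136 samples)."""
    return SimulationConfig(n_genes=300, n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
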