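import numpy as np
import pytest

from zinbcap.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """50 genes x 300 cells, two groups, with DE/DZI truth and capture."""
    cfg = SimulationConfig(n_genes=50, n_cells=300, de_fraction=0.1,
                           dzi_fraction=0.1, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
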