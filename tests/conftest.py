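import numpy as np
import pytest

from cochleapharm.data import CountMatrix
from cochleapharm.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully featured synthetic design for fast tests."""
    return SimulationConfig(n_genes=400, n_reps=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_counts(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def random_counts(rng) -> CountMatrix:
    """A 50 x 12 random count matrix with a handful of all-zero rows."""
    mat = rng.poisson(30.0, size=(50, 12))
    mat[rng.choice(50, 5, replace=False), :] = 0
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j:02d}" for j in range(12)]
    return CountMatrix(genes, samples, mat)
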