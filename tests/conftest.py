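import numpy as np
import pandas as pd
import pytest

from rmcblup import SimulationConfig, simulate_metagenome, simulate_population


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_animals=300, n_snps=400, n_tags=500,
                            n_flocks=3, n_years=3, n_flowcells=2, seed=11)


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_metagenome(small_config, small_population):
    _, _, truth = small_population
    return simulate_metagenome(truth, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_kernel(n: int, rng: np.random.Generator, rank: int | None = None):
    """A random PSD kernel with unit average diagonal."""
    k = rank or n + 5
    A = rng.standard_normal((n, k))
    K = A @ A.T / k
    return K / np.diag(K).mean()
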