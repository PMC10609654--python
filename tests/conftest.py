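import numpy as np
import pytest

import massimpute as mi


@pytest.fixture(scope="session")
def default_config() -> mi.SuperPopulationConfig:
    return mi.SuperPopulationConfig(N=10_000)


@pytest.fixture(scope="session")
def population(default_config) -> mi.FinitePopulation:
    return mi.generate_population(default_config, np.random.default_rng(12345))


@pytest.fixture(scope="session")
def sample_pair(population):
    """One (S_A, S_B) pair drawn from the shared population."""
    rng = np.random.default_rng(2024)
    sA = mi.draw_srswor(population, 500, rng)
    model = mi.calibrate_selection(population)
    sB = mi.draw_poisson(population, model, rng)
    return sA, sB
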