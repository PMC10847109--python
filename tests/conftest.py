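import numpy as np
import pytest

from reprotri import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_females=4000,
        n_males=2000,
        n_snps_per_exposure=20,
        n_metabolites=10,
        n_factors=6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
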