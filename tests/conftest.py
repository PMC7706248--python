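import numpy as np
import pandas as pd
import pytest

from poolvar.sim import SimulationConfig, sample_read_counts, simulate_truth

EQUAL_GROUPS = {"wild": 0.25, "landrace": 0.25, "historic": 0.25, "modern": 0.25}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """12 accessions, 3 per germplasm group, one divergent wild accession."""
    return SimulationConfig(
        n_accessions=12,
        n_amplicons=4,
        n_shared_sites=30,
        group_fractions=EQUAL_GROUPS,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return sample_read_counts(small_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
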