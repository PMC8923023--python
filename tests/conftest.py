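import numpy as np
import pytest

from orthoclust import SimConfig, simulate_dataset
from orthoclust.io import blocks_from_tables
from orthoclust.standardize import assemble_matrix


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise dataset: 60 families, 8 planted modules of 4, no dropout."""
    cfg = SimConfig(
        seed=11,
        n_families=60,
        n_modules=8,
        module_size_range=(4, 4),
        noise_sd=0.05,
        missing_family_rate=0.0,
        low_coverage_rate=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    """Full-profile assembled matrix for the small dataset."""
    ds = small_dataset
    blocks = blocks_from_tables(ds.tables, ds.block_layout)
    return assemble_matrix(
        blocks, ds.ortholog_map, list(ds.config.species_list)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
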