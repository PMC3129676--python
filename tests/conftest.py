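import numpy as np
import pytest

from metaconserve.pipeline import run_pipeline
from metaconserve.simdata import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def small_config():
    """A small but complete community: 3 taxa, contamination spiked."""
    return CommunityConfig(
        n_taxa=3,
        genes_per_taxon=30,
        n_dna_reads=1500,
        n_rna_reads=1000,
        rrna_fraction=0.05,
        duplicate_fraction=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    return simulate_community(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    """One full pipeline run shared across tests."""
    return run_pipeline(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
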