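import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssbmap import Genome, SimulationConfig, simulate_genome_and_genes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully featured simulated experiment."""
    return SimulationConfig(
        seed=7,
        genome_length=1_500_000,
        n_genes=30,
        gene_length_bounds=(5_000, 30_000),
        background_rate=0.5,
        breaks_per_kb_at_reference_tpm=3.0,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, genes = simulate_genome_and_genes(small_config)
    return genome, genes


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": "AAACATTGCAAA", "chr2": "ACGTACGTACGTACGT"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
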