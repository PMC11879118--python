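import pytest

from epromoter import SyntheticConfig, generate_world


SMALL = SyntheticConfig(
    n_chromosomes=2,
    chrom_length_bp=1_500_000,
    n_genes=120,
    n_gwas_leads=60,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_world():
    """A miniature world shared across module tests (seeded, deterministic)."""
    return generate_world(SMALL)
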