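import pytest

from isonet.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The standard toy study: 50 genes, 10 tumor vs 20 normal, gap 0.6."""
    return generate_world(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_world():
    """A small world for oracle comparisons (<= 20 proteins)."""
    return generate_world(
        SyntheticConfig(
            n_genes=8,
            isoforms_per_gene=(2, 3),
            n_tumor=4,
            n_normal=8,
            edge_density=0.4,
            seed=7,
        )
    )
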