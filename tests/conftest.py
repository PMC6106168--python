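import pytest

from mitocomp.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def genome():
    """One deterministic synthetic mitogenome shared across tests."""
    return generate_genome(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def genome_trio():
    """Three genomes with different seeds and biases for cross-genome stats."""
    return [
        generate_genome(SyntheticConfig(seed=s, at_target=at, codon_bias=cb))
        for s, at, cb in [(1, 0.60, 1.0), (2, 0.65, 2.0), (3, 0.70, 4.0)]
    ]
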