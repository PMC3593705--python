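import pytest

from mitochar import GenomeSpec, generate_mitogenome


@pytest.fixture(scope="session")
def default_genome_truth():
    """One fully verified synthetic genome at the default study conditions."""
    return generate_mitogenome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def default_genome(default_genome_truth):
    return default_genome_truth[0]


@pytest.fixture(scope="session")
def default_truth(default_genome_truth):
    return default_genome_truth[1]
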