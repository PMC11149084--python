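import pytest
from hypothesis import settings

from bloomid import CommunitySpec, build_index, make_genomes, make_reads

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_spec() -> CommunitySpec:
    """Small universe: 6 genomes, first 3 sequenced error-free."""
    return CommunitySpec(
        g_total=6, present_ids=[1, 2, 3], genome_length=3_000, coverage=2.0,
        read_length=75, substitution_error_rate=0.0, master_seed=11,
    )


@pytest.fixture(scope="session")
def toy_genomes(toy_spec):
    return make_genomes(toy_spec)


@pytest.fixture(scope="session")
def toy_index(toy_genomes):
    return build_index(toy_genomes, k=15, n=3, master_seed=5)


@pytest.fixture(scope="session")
def toy_reads(toy_genomes, toy_spec):
    return make_reads(toy_genomes, toy_spec)
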