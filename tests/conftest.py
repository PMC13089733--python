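import pytest
from hypothesis import HealthCheck, settings

from mitostruct.codon_usage import load_genetic_code
from mitostruct.genome_io import load_reference_composition, load_reference_record
from mitostruct.synthetic import reference_like_genome_spec, simulate_mitogenome

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_record():
    """The packaged H. atra annotation table (37 features, 15,788 bp)."""
    return load_reference_record()


@pytest.fixture(scope="session")
def reference_composition():
    """The published per-gene composition/skew table."""
    return load_reference_composition()


@pytest.fixture(scope="session")
def code9():
    return load_genetic_code(9)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One reference-architecture synthetic genome shared across tests."""
    return simulate_mitogenome(reference_like_genome_spec(seed=7))
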