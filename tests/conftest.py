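import pytest
from hypothesis import HealthCheck, settings

from cyanophage import recruitment as rec
from cyanophage import synthetic_data as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb, 20-gene synthetic genome with its ground-truth layout."""
    spec = syn.GenomeSpec(length=20_000, gc=0.60, n_genes=20, seed=3)
    genome, genes = syn.generate_genome(spec)
    return genome, genes


@pytest.fixture(scope="session")
def target(small_genome):
    genome, genes = small_genome
    return rec.TargetPhage(genome, genes)


@pytest.fixture(scope="session")
def panel(target):
    """Two groups of 60–65%-identity relatives of the target."""
    return syn.build_panel(
        target, [("MPP-A", 2, 0.65), ("MPP-B2", 2, 0.60)], seed=7
    )
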