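import pytest
from hypothesis import HealthCheck, settings

from plastcodon.genome_io import CdsRecord
from plastcodon.synthetic import SyntheticSpec, generate_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cds(codons, gene="g", fpkm=None):
    """Build a CdsRecord straight from a codon list."""
    return CdsRecord(gene, "".join(codons), fpkm=fpkm)


@pytest.fixture(scope="session")
def default_genome():
    """The canonical 40-gene two-group synthetic plastome (seed 0)."""
    return generate_genome(SyntheticSpec(n_genes=40, seed=0))
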