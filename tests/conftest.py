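import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from codonblosum import (
    DomainMap,
    GeneModel,
    SubstitutionWeights,
    enumerate_events,
    make_toy_gene,
)


@pytest.fixture(scope="session")
def uniform_weights():
    return SubstitutionWeights.uniform()


@pytest.fixture(scope="session")
def toy_gene():
    """A 60-codon random gene, fixed seed."""
    return make_toy_gene(60, seed=20260926)


@pytest.fixture(scope="session")
def toy_table(toy_gene, uniform_weights):
    """Whole-CDS neutral event table for the toy gene."""
    return enumerate_events(toy_gene, range(1, toy_gene.L + 1), uniform_weights)


@pytest.fixture(scope="session")
def toy_domains(toy_gene):
    return DomainMap(
        gene_id=toy_gene.gene_id,
        intervals=(("Nterm", 5, 20), ("Core", 25, 45), ("Cterm", 50, 58)),
    )


@pytest.fixture()
def small_gene():
    """ATG CGT TGG AAA: one arginine, one tryptophan, one lysine codon."""
    return GeneModel(gene_id="G1", cds="ATGCGTTGGAAA")
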