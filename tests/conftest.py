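import pytest

from ferttx.models import GeneModel, IsoformChain
from ferttx.synthetic_data import NestedExonSpec, SyntheticConfig


@pytest.fixture
def plus_gene():
    """Two-exon plus-strand gene: exons 101-300 and 501-800, CDS 151-750."""
    return GeneModel(
        gene_id="gp", chrom="chr1", strand="+",
        exons=((101, 300), (501, 800)), cds_start=151, cds_end=750,
    )


@pytest.fixture
def minus_gene():
    """Two-exon minus-strand gene with the same structure."""
    return GeneModel(
        gene_id="gm", chrom="chr1", strand="-",
        exons=((101, 300), (501, 800)), cds_start=151, cds_end=750,
    )


@pytest.fixture
def three_exon_reference():
    """Reference chain with introns (101,200), (301,400)."""
    return IsoformChain(
        isoform_id="ref1", gene_id="g", chrom="chr1", strand="+",
        exons=((1, 100), (201, 300), (401, 500)), source="reference",
    )


@pytest.fixture
def small_config():
    return SyntheticConfig(
        seed=11, n_genes=3, chrom_length=200_000,
        tissues=("liver", "lung"),
    )


@pytest.fixture
def nested_config():
    return SyntheticConfig(
        seed=5, n_genes=3, chrom_length=200_000,
        nested_exon_spec=NestedExonSpec(host_gene="g2", guest_gene="gx"),
    )
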