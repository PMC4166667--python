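import pytest

from auxfam import synthetic_data as sd
from auxfam.io_core import AnnotationSet, GeneModel, SequenceSet


@pytest.fixture(scope="session")
def toy_genome():
    """8-chromosome genome with the 3/3/1/4/2/0/1/3 gene layout."""
    return sd.generate_genome(8, [3, 3, 1, 4, 2, 0, 1, 3], seed=101)


@pytest.fixture(scope="session")
def family_proteins():
    """17 canonical family proteins plus 5 decoys lacking the PB1 region."""
    archs = sd.canonical_family_architectures(17) + sd.decoy_architectures(5)
    return sd.generate_proteins(archs, seed=202)


@pytest.fixture
def two_exon_gene():
    return GeneModel(
        name="g1", chromosome="chr1", strand="+", start=101, end=700,
        exons=[(101, 300), (401, 700)], orf_length_nt=500,
    )


@pytest.fixture
def simple_annotation(two_exon_gene):
    single = GeneModel(
        name="g2", chromosome="chr2", strand="-", start=1001, end=1600,
        exons=[(1001, 1600)], orf_length_nt=600,
    )
    return AnnotationSet([two_exon_gene, single], source="test")


def make_seqset(*pairs, alphabet="dna"):
    return SequenceSet(list(pairs), alphabet=alphabet)
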