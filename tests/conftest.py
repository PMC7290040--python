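import pytest

from circkit.io_formats import AnnotationSet, CircRecord, Exon, Gene, GenomeSequence
from circkit.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One default synthetic data set shared across tests."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(sim, tmp_path_factory):
    from circkit.simulate import write_fixture_tree

    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_tree(sim, out)


@pytest.fixture
def tiny_genome():
    g = GenomeSequence()
    g.add("chr1", "AAACGTTTGG")
    g.add("chr2", "TTAGCCCGTA")
    return g


@pytest.fixture
def two_gene_annotation():
    """Two genes on chr1: geneA with exons [100,200) [300,400) [500,600),
    geneB with exons [1000,1100) [1200,1300); intergenic elsewhere."""
    genes = [
        Gene("geneA", "chr1", "+", 100, 600),
        Gene("geneB", "chr1", "-", 1000, 1300),
    ]
    exons = [
        Exon("geneA", "txA", "chr1", 100, 200, "+"),
        Exon("geneA", "txA", "chr1", 300, 400, "+"),
        Exon("geneA", "txA", "chr1", 500, 600, "+"),
        Exon("geneB", "txB", "chr1", 1000, 1100, "-"),
        Exon("geneB", "txB", "chr1", 1200, 1300, "-"),
    ]
    return AnnotationSet(genes, exons)


def make_circ(start, end, chrom="chr1", strand="+", circ_id=""):
    return CircRecord(chrom, start, end, strand, circ_id)
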