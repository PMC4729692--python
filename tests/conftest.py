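import numpy as np
import pytest

from epistate.genome_io import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genes():
    """Three genes on two chromosomes, mixed strands."""
    def gene(chrom, start, end, strand, gid):
        return GeneModel(GenomicInterval(chrom, start, end, strand, gid,
                                         "gene_body"), gid)
    return [
        gene("chr1", 10_000, 20_000, "+", "gA"),
        gene("chr1", 40_000, 55_000, "-", "gB"),
        gene("chr2", 5_000, 9_000, "+", "gC"),
    ]
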