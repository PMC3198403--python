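import numpy as np
import pandas as pd
import pytest

from strandtools.annotation import GeneModel, build_intron_db, derive_ncrs
from strandtools.intervals import GenomicInterval
from strandtools.simulate import simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_genome():
    """20 well-separated multi-exon genes on a 600 kb chromosome."""
    return simulate_annotation(n_genes=20, chrom_length=600_000, seed=11)


@pytest.fixture(scope="session")
def small_counts(small_genome):
    lengths = pd.Series(
        {gid: g.exonic_length for gid, g in small_genome.genes.items()}
    )
    counts, truth = simulate_counts(lengths, seed=12)
    return lengths, counts, truth


@pytest.fixture
def two_exon_gene():
    return GeneModel(
        "gA",
        "chr1",
        "+",
        [
            GenomicInterval("chr1", 100, 200, "+"),
            GenomicInterval("chr1", 300, 400, "+"),
        ],
    )


@pytest.fixture
def two_exon_gene_minus():
    return GeneModel(
        "gB",
        "chr1",
        "-",
        [
            GenomicInterval("chr1", 100, 200, "-"),
            GenomicInterval("chr1", 300, 400, "-"),
        ],
    )
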