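"""Synthetic data generation for every pipeline stage.

The generator emulates the study design the pipeline targets: a compact
plant-like genome with non-overlapping, well-separated multi-exon genes
(so non-coding regions exist), strand-specific single-end 35 nt reads
produced by dUTP chemistry (reads align antisense to their source
transcript) with a small antisense contamination rate, replicate-pooled
gene counts from the two-component Poisson model (background rate lambda0
for silent genes, Gamma-distributed rates for expressed ones), intron
counts proportional to host-gene expression times a Gamma-distributed
retention rate, and multiplexed FASTQ with indexed read prefixes and
substitution errors.

Every stochastic entry point takes an explicit seed and is deterministic
under it.  Truth labels (expressed indicators, true rates, source units,
generating indices) are returned alongside every output so detection,
calibration and demultiplexing accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntronRecord, NcrInterval, build_intron_db
from .intervals import AlignmentRecord, GenomicInterval, opposite_strand

__all__ = [
    "SimulatedGenome",
    "simulate_annotation",
    "write_annotation",
    "simulate_counts",
    "simulate_intron_counts",
    "simulate_alignments",
    "simulate_ncr_alignments",
    "simulate_indexed_fastq",
    "write_sam",
    "DEFAULT_INDEX_SETS",
]

# Balanced example index sets shipped with the package (each position uses
# every base at least twice across the set; min pairwise Hamming distance 2).
DEFAULT_INDEX_SETS: dict[str, tuple[str, ...]] = {
    "set11x5": (
        "ACACG", "ACGTA", "AGTCC", "CATGA", "CGATC", "CTCAG",
        "GACTT", "GGTAC", "GTGCA", "TCAGT", "TGCAT",
    ),
    "set4x7": ("ACGTACG", "CATCGTA", "GTCAGTC", "TGAGCAT"),
}


@dataclass
class SimulatedGenome:
    """A synthetic genome: sequence, gene models and derived assets."""

    genes: dict[str, GeneModel]
    chrom_sizes: dict[str, int]
    sequence: dict[str, str]

    @property
    def introns(self) -> list[IntronRecord]:
        return build_intron_db(self.genes)


def simulate_annotation(
    n_genes: int = 100,
    chrom_length: int = 1_000_000,
    n_exons_range: tuple[int, int] = (1, 5),
    exon_length_range: tuple[int, int] = (150, 400),
    intron_length_range: tuple[int, int] = (80, 300),
    min_spacing: int = 12_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> SimulatedGenome:
    """Lay out non-overlapping genes along one chromosome.

    Genes are separated by at least ``min_spacing`` bp (default 12 kb, so
    5 kb-padded exons still leave non-empty NCRs between genes), receive a
    random strand, and a uniform random ACGT sequence backs the whole
    chromosome.  Raises if the requested genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    pos = int(rng.integers(min_spacing, 2 * min_spacing))
    for i in range(n_genes):
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exon_lens = rng.integers(
            exon_length_range[0], exon_length_range[1] + 1, size=n_ex
        )
        intron_lens = rng.integers(
            intron_length_range[0], intron_length_range[1] + 1, size=max(n_ex - 1, 0)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cursor = pos
        for j, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, cursor, cursor + int(el), strand))
            cursor += int(el)
            if j < n_ex - 1:
                cursor += int(intron_lens[j])
        if cursor > chrom_length - min_spacing:
            raise ValueError(
                f"cannot pack {n_genes} genes into {chrom_length} bp with "
                f"{min_spacing} bp spacing (failed at gene {i + 1})"
            )
        gid = f"gene{i + 1:04d}"
        genes[gid] = GeneModel(gid, chrom, strand, exons)
        pos = cursor + min_spacing + int(rng.integers(0, min_spacing))

    seq = "".join(rng.choice(list("ACGT"), size=chrom_length))
    return SimulatedGenome(
        genes=genes, chrom_sizes={chrom: chrom_length}, sequence={chrom: seq}
    )


def write_annotation(
    sim: SimulatedGenome,
    gff3_path: str | Path | None = None,
    gtf_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
) -> None:
    """Serialise a simulated genome as GFF3 and/or GTF plus FASTA.

    Each gene is written as one gene + one transcript (``<gene>.1``) with
    its exon chain; coordinates follow the 1-based inclusive convention of
    both formats.
    """
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sim.genes.values():
                s = g.span
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{s.start + 1}\t{s.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                tid = f"{g.gene_id}.1"
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{s.start + 1}\t{s.end}\t.\t"
                    f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for k, ex in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\tID={tid}.exon{k};Parent={tid}\n"
                    )
    if gtf_path is not None:
        with open(gtf_path, "w") as fh:
            for g in sim.genes.values():
                tid = f"{g.gene_id}.1"
                for ex in g.exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in sim.sequence.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    lengths: pd.Series,
    lambda0: float = 0.001,
    pi0: float = 0.4,
    shape: float = 2.0,
    rate: float = 20.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-replicate gene counts from the two-component model.

    Each gene is silent with probability ``pi0`` (rate lambda0) or
    expressed with rate lambda_g ~ Gamma(shape, rate); replicate counts
    are Poisson(L_g * lambda_g / n) so the pooled mean is L_g * lambda_g.

    Returns (counts: genes x replicates, truth: expressed flag and true
    rate per gene).
    """
    rng = np.random.default_rng(seed)
    L = lengths.to_numpy(dtype=float)
    n_genes = L.size
    expressed = rng.random(n_genes) >= pi0
    lam = np.full(n_genes, lambda0)
    lam[expressed] = rng.gamma(shape, 1.0 / rate, size=int(expressed.sum()))
    mean_per_rep = L * lam / n_replicates
    counts = rng.poisson(mean_per_rep[:, None], size=(n_genes, n_replicates))
    cols = [f"rep{j + 1}" for j in range(n_replicates)]
    counts_df = pd.DataFrame(counts, index=lengths.index, columns=cols)
    truth = pd.DataFrame(
        {"expressed": expressed, "lambda": lam}, index=lengths.index
    )
    return counts_df, truth


def simulate_intron_counts(
    intron_lengths: pd.Series,
    gene_expression: pd.Series,
    lambda0: float = 0.001,
    retained_fraction: float = 0.1,
    r_shape: float = 2.0,
    r_mean: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw pooled intron counts from the retention model.

    ``gene_expression`` maps each intron (same index as
    ``intron_lengths``) to its host gene's expression proxy E_g.  Retained
    introns (fraction ``retained_fraction``) get rate E_g * r with
    r ~ Gamma(r_shape, r_shape / r_mean); the rest sit at the background
    lambda0.  ``r_mean`` defaults so that the average retained intron has
    10x the background density, a clearly-but-not-trivially detectable
    signal.
    """
    rng = np.random.default_rng(seed)
    L = intron_lengths.to_numpy(dtype=float)
    E = gene_expression.reindex(intron_lengths.index).to_numpy(dtype=float)
    n = L.size
    if r_mean is None:
        mean_E = E[E > 0].mean() if (E > 0).any() else 1.0
        r_mean = 10.0 * lambda0 / mean_E
    retained = rng.random(n) < retained_fraction
    retained &= E > 0  # cannot retain an unexpressed gene's intron
    r = np.zeros(n)
    r[retained] = rng.gamma(r_shape, r_mean / r_shape, size=int(retained.sum()))
    mean = np.where(retained, L * E * r, L * lambda0)
    x = rng.poisson(mean)
    table = pd.DataFrame(
        {"X": x, "L": L.astype(int), "E": E}, index=intron_lengths.index
    )
    truth = pd.DataFrame(
        {"retained": retained, "r": r}, index=intron_lengths.index
    )
    return table, truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _place_read_in_gene(
    gene: GeneModel, u: float, read_length: int
) -> tuple[int, int]:
    """Genomic (start, end) of a read whose 5' spliced position is at
    fraction ``u`` of the transcript body; the read is clipped at the exon
    boundary it would cross (single-block alignments)."""
    L = gene.exonic_length
    t = min(int(u * L), L - 1)
    if gene.strand == "-":
        t = L - 1 - t
    # locate exon containing spliced (plus-orientation) offset t
    acc = 0
    for ex in gene.exons:
        if t < acc + ex.length:
            g0 = ex.start + (t - acc)
            g1 = min(g0 + read_length, ex.end)
            return g0, g1
        acc += ex.length
    raise AssertionError("spliced offset out of range")


def simulate_alignments(
    counts: pd.Series,
    genes: Mapping[str, GeneModel],
    antisense_rate: float = 0.02,
    bias: str | None = None,
    read_length: int = 35,
    orientation: str = "reverse",
    seed: int = 0,
    read_prefix: str = "read",
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Place stranded reads for the given per-gene counts.

    Read 5' positions are uniform along the spliced body, or 3'-weighted
    with ``bias="3prime"`` (linearly increasing density, emulating
    oligo-dT capture plus degradation).  Each read is antisense with
    probability ``antisense_rate``; under the default dUTP (``reverse``)
    orientation a sense read aligns opposite the gene strand.  Reads are
    clipped at exon junctions so each alignment is a single block.

    Returns the alignments and a truth table (read id, gene, class).
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    truth_rows = []
    k = 0
    for gid, n_reads in counts.items():
        gene = genes[gid]
        for _ in range(int(n_reads)):
            u = np.sqrt(rng.random()) if bias == "3prime" else rng.random()
            g0, g1 = _place_read_in_gene(gene, u, read_length)
            is_anti = rng.random() < antisense_rate
            if orientation == "reverse":
                strand = gene.strand if is_anti else opposite_strand(gene.strand)
            else:
                strand = opposite_strand(gene.strand) if is_anti else gene.strand
            k += 1
            rid = f"{read_prefix}{k:07d}"
            records.append(AlignmentRecord(rid, gene.chrom, g0, g1, strand))
            truth_rows.append(
                {"read_id": rid, "gene_id": gid,
                 "class": "antisense" if is_anti else "sense"}
            )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "class"])
    return records, truth


def simulate_ncr_alignments(
    ncr_counts: pd.Series,
    ncrs: Sequence[NcrInterval],
    read_length: int = 35,
    seed: int = 0,
    read_prefix: str = "bg",
) -> list[AlignmentRecord]:
    """Uniformly placed background reads within NCRs, random strand."""
    rng = np.random.default_rng(seed)
    by_name = {rec.name: rec for rec in ncrs}
    records: list[AlignmentRecord] = []
    k = 0
    for name, n_reads in ncr_counts.items():
        rec = by_name[name]
        iv = rec.interval
        span = max(iv.length - read_length, 1)
        for _ in range(int(n_reads)):
            g0 = iv.start + int(rng.integers(0, span))
            g1 = min(g0 + read_length, iv.end)
            strand = "+" if rng.random() < 0.5 else "-"
            k += 1
            records.append(
                AlignmentRecord(f"{read_prefix}{k:07d}", iv.chrom, g0, g1, strand)
            )
    return records


def write_sam(
    alignments: Sequence[AlignmentRecord],
    chrom_sizes: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write single-block alignments as a plain-text SAM file."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    ref_ids = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_id = ref_ids[a.chrom]
            seg.reference_start = a.start
            seg.cigarstring = f"{a.length}M"
            seg.flag = 16 if a.strand == "-" else 0
            seg.mapping_quality = 42
            seg.query_sequence = "N" * a.length
            fh.write(seg)


# ---------------------------------------------------------------------------
# multiplexed FASTQ
# ---------------------------------------------------------------------------

def simulate_indexed_fastq(
    reads_per_index: Mapping[str, int],
    n_common: int = 1,
    common_base: str = "T",
    error_rate: float = 0.0,
    read_length: int = 35,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate multiplexed reads: index + common base(s) + random insert.

    Substitution errors are injected independently at ``error_rate`` per
    base over the whole read (index bases included — that is what the
    one-mismatch rescue must cope with).  Returns the reads as
    (id, sequence, quality) tuples plus a truth table with each read's
    generating index.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    k = 0
    for index, n_reads in reads_per_index.items():
        prefix = index.upper() + common_base * n_common
        insert_len = read_length - len(prefix)
        if insert_len < 0:
            raise ValueError("read_length shorter than the index prefix")
        for _ in range(int(n_reads)):
            insert = rng.choice(bases, size=insert_len)
            seq = np.concatenate(
                [np.frombuffer(prefix.encode(), dtype=np.uint8), insert]
            )
            if error_rate > 0:
                hit = rng.random(seq.size) < error_rate
                if hit.any():
                    # substitute with one of the three *other* bases
                    cur = seq[hit]
                    shift = rng.integers(1, 4, size=cur.size)
                    pos = np.searchsorted(bases, cur)
                    seq = seq.copy()
                    seq[hit] = bases[(pos + shift) % 4]
            k += 1
            rid = f"mread{k:07d}"
            reads.append((rid, seq.tobytes().decode(), "I" * seq.size))
            truth_rows.append({"read_id": rid, "index": index})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "index"])
    return reads, truth
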