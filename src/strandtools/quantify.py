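"""Strand-aware read counting and coverage diagnostics.

The dUTP strand-specific chemistry sequences the strand *opposite* the
source transcript, so under the default ``orientation="reverse"`` an
alignment whose strand is opposite the gene's strand is a *sense* read.
``orientation="forward"`` supports protocols that sequence the transcript
strand directly.

Counting rules (configurable, see the methods note):

* only primary, uniquely-mapped alignments are counted;
* a read counts toward a gene when it overlaps the gene's exonic bases by
  >= 1 bp; reads overlapping the exon space of more than one gene are
  discarded as ambiguous;
* a read counts toward an intron only when at least half of the read lies
  inside the intron, so junction-straddling reads are not taken as
  retention evidence;
* NCR counting is strand-agnostic and a boundary-spanning read goes to the
  region it overlaps most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, IntronRecord, NcrInterval, equal_fraction_edges
from .intervals import AlignmentRecord, opposite_strand

__all__ = [
    "StrandedCountTable",
    "assign_read_strand",
    "count_gene_reads",
    "count_intron_reads",
    "count_ncr_reads",
    "compute_rpkm",
    "rpkm_table",
    "gene_body_coverage_profile",
    "antisense_fraction_profile",
    "read_alignments_sam",
    "read_alignments_bed",
    "write_alignments_bed",
]


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

def read_alignments_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read single-end alignments from SAM/BAM via pysam.

    Unmapped reads are dropped; secondary/supplementary flags set
    ``is_primary=False`` and mapping quality 0 sets ``is_unique=False``
    (the convention of bowtie-style reporting for multi-mappers).
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    is_unique=aln.mapping_quality > 0,
                )
            )
    return records


def read_alignments_bed(path: str | Path) -> list[AlignmentRecord]:
    """Read alignments from 6-column BED (chrom start end name score strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
        comment="#",
    )
    return [
        AlignmentRecord(r.name, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_alignments_bed(
    alignments: Iterable[AlignmentRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")


# ---------------------------------------------------------------------------
# strand logic
# ---------------------------------------------------------------------------

def assign_read_strand(
    alignment_strand: str, gene_strand: str, orientation: str = "reverse"
) -> str:
    """Classify an alignment as 'sense' or 'antisense' to a gene.

    Under ``reverse`` (the dUTP convention) reads map antisense to their
    source transcript, so opposite strands mean a sense read; ``forward``
    flips the rule.
    """
    if orientation not in ("reverse", "forward"):
        raise ValueError(f"unknown orientation {orientation!r}")
    same = alignment_strand == gene_strand
    if orientation == "reverse":
        return "antisense" if same else "sense"
    return "sense" if same else "antisense"


def _filter_alignments(
    alignments: Iterable[AlignmentRecord],
    unique_only: bool,
    primary_only: bool,
) -> list[AlignmentRecord]:
    return [
        a
        for a in alignments
        if (a.is_unique or not unique_only) and (a.is_primary or not primary_only)
    ]


def _exon_tree(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for ex in gene.exons:
            tree.addi(ex.start, ex.end, gene.gene_id)
    return trees


def _warn_unknown_chrom(chrom: str, known: set[str], seen: set[str]) -> None:
    if chrom not in seen:
        seen.add(chrom)
        warnings.warn(f"alignment on unknown chromosome {chrom!r} skipped",
                      stacklevel=3)


# ---------------------------------------------------------------------------
# count table container
# ---------------------------------------------------------------------------

@dataclass
class StrandedCountTable:
    """Per-gene sense/antisense counts per replicate, plus intron and NCR
    counts and per-replicate library sizes.

    ``sense``/``antisense`` are (genes x replicates) DataFrames; ``introns``
    is (introns x replicates) indexed by intron name; ``ncr`` likewise by
    NCR name.  ``totals`` holds the mapped-read count N_j per replicate.
    """

    sense: pd.DataFrame
    antisense: pd.DataFrame
    introns: pd.DataFrame | None = None
    ncr: pd.DataFrame | None = None
    totals: pd.Series | None = None

    @property
    def n_replicates(self) -> int:
        return self.sense.shape[1]

    @property
    def pooled_sense(self) -> pd.Series:
        """Y_g: replicate-pooled sense counts."""
        return self.sense.sum(axis=1)

    @property
    def pooled_antisense(self) -> pd.Series:
        return self.antisense.sum(axis=1)

    @property
    def unstranded(self) -> pd.DataFrame:
        """Sense + antisense, the non-strand-specific recombination."""
        return self.sense + self.antisense

    @classmethod
    def from_replicates(
        cls,
        per_rep: Sequence[tuple[pd.Series, pd.Series]],
        totals: Sequence[int] | None = None,
        introns: Sequence[pd.Series] | None = None,
        ncr: Sequence[pd.Series] | None = None,
    ) -> "StrandedCountTable":
        reps = [f"rep{j + 1}" for j in range(len(per_rep))]
        sense = pd.concat([s for s, _ in per_rep], axis=1, keys=reps)
        anti = pd.concat([a for _, a in per_rep], axis=1, keys=reps)
        return cls(
            sense=sense,
            antisense=anti,
            introns=(
                pd.concat(list(introns), axis=1, keys=reps)
                if introns is not None
                else None
            ),
            ncr=pd.concat(list(ncr), axis=1, keys=reps) if ncr is not None else None,
            totals=(
                pd.Series(list(totals), index=reps, name="total_mapped")
                if totals is not None
                else None
            ),
        )


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_gene_reads(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    orientation: str = "reverse",
    mode: str = "stranded",
    unique_only: bool = True,
    primary_only: bool = True,
    known_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Count reads per gene, split by sense/antisense.

    A read counts toward a gene when it overlaps >= 1 bp of the gene's exon
    space; reads touching the exon space of more than one gene are
    discarded as ambiguous.  Returns a DataFrame indexed by gene_id with
    columns ``sense`` and ``antisense`` (summed into ``count`` when
    ``mode="unstranded"``) and a ``total_mapped`` attribute in ``.attrs``.
    """
    if mode not in ("stranded", "unstranded"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    by_id = {g.gene_id: g for g in gene_list}
    trees = _exon_tree(gene_list)
    if known_chroms is None:
        known_chroms = set(trees)

    alignments = _filter_alignments(alignments, unique_only, primary_only)
    sense = {g.gene_id: 0 for g in gene_list}
    anti = {g.gene_id: 0 for g in gene_list}
    warned: set[str] = set()
    for a in alignments:
        if a.chrom not in known_chroms:
            _warn_unknown_chrom(a.chrom, known_chroms, warned)
            continue
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(a.start, a.end)}
        if len(hits) != 1:
            continue  # no overlap, or ambiguous between genes
        gid = hits.pop()
        cls = assign_read_strand(a.strand, by_id[gid].strand, orientation)
        if cls == "sense":
            sense[gid] += 1
        else:
            anti[gid] += 1

    df = pd.DataFrame(
        {"sense": pd.Series(sense), "antisense": pd.Series(anti)}
    ).loc[[g.gene_id for g in gene_list]]
    df.index.name = "gene_id"
    if mode == "unstranded":
        df = pd.DataFrame({"count": df["sense"] + df["antisense"]})
    df.attrs["total_mapped"] = len(alignments)
    return df


def count_intron_reads(
    alignments: Iterable[AlignmentRecord],
    introns: Sequence[IntronRecord],
    genes: Mapping[str, GeneModel],
    orientation: str = "reverse",
    min_overlap_fraction: float = 0.5,
    unique_only: bool = True,
    primary_only: bool = True,
) -> pd.Series:
    """Count sense-orientation reads per intron.

    A read is assigned to the intron covering at least
    ``min_overlap_fraction`` of its length (default one half); reads tied
    between two introns at the threshold are discarded.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in introns:
        trees.setdefault(rec.interval.chrom, IntervalTree()).addi(
            rec.interval.start, rec.interval.end, rec
        )
    counts = {rec.name: 0 for rec in introns}
    alignments = _filter_alignments(alignments, unique_only, primary_only)
    for a in alignments:
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        best: list[IntronRecord] = []
        best_ov = 0
        for iv in tree.overlap(a.start, a.end):
            ov = min(a.end, iv.end) - max(a.start, iv.begin)
            if ov > best_ov:
                best, best_ov = [iv.data], ov
            elif ov == best_ov and ov > 0:
                best.append(iv.data)
        if len(best) != 1 or best_ov < min_overlap_fraction * a.length:
            continue
        rec = best[0]
        gene = genes[rec.gene_id]
        if assign_read_strand(a.strand, gene.strand, orientation) == "sense":
            counts[rec.name] += 1
    out = pd.Series(counts, name="count")
    out.index.name = "intron"
    return out


def count_ncr_reads(
    alignments: Iterable[AlignmentRecord],
    ncrs: Sequence[NcrInterval],
    unique_only: bool = True,
    primary_only: bool = True,
) -> pd.Series:
    """Strand-agnostic read counts per NCR; a boundary-spanning read counts
    toward the NCR it overlaps most (ties discarded)."""
    trees: dict[str, IntervalTree] = {}
    for rec in ncrs:
        trees.setdefault(rec.interval.chrom, IntervalTree()).addi(
            rec.interval.start, rec.interval.end, rec
        )
    counts = {rec.name: 0 for rec in ncrs}
    for a in _filter_alignments(alignments, unique_only, primary_only):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        best: list[NcrInterval] = []
        best_ov = 0
        for iv in tree.overlap(a.start, a.end):
            ov = min(a.end, iv.end) - max(a.start, iv.begin)
            if ov > best_ov:
                best, best_ov = [iv.data], ov
            elif ov == best_ov and ov > 0:
                best.append(iv.data)
        if len(best) == 1:
            counts[best[0].name] += 1
    out = pd.Series(counts, name="count")
    out.index.name = "ncr"
    return out


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

def compute_rpkm(count, exonic_length, total_mapped) -> float | np.ndarray:
    """Reads per kilobase of exon model per million mapped reads:
    ``1e9 * count / (exonic_length * total_mapped)``."""
    exonic_length = np.asarray(exonic_length, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if np.any(exonic_length <= 0):
        raise ValueError("exonic_length must be positive")
    if np.any(total_mapped <= 0):
        raise ValueError("total_mapped must be positive")
    out = 1e9 * np.asarray(count, dtype=float) / (exonic_length * total_mapped)
    return out if out.ndim else float(out)


def rpkm_table(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    """Per-gene x replicate RPKM plus the across-replicate sum E_g.

    ``counts``: (genes x replicates); ``lengths``: L_g per gene;
    ``totals``: N_j per replicate.  E_g (column ``E``) is the sum of RPKM
    values across replicates, the expression proxy used to normalise the
    intron-retention rate.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for genes: {missing[:5]}")
    rpkm = 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)
    rpkm["E"] = rpkm.sum(axis=1)
    return rpkm


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def _per_gene_coverage(
    alignments: Iterable[AlignmentRecord],
    gene_list: Sequence[GeneModel],
    orientation: str,
    unique_only: bool = True,
    primary_only: bool = True,
) -> dict[str, dict[str, np.ndarray]]:
    """Base-level sense/antisense coverage over each gene's spliced body.

    Only reads unambiguously assigned to a single gene contribute, matching
    the counting rules.
    """
    trees = _exon_tree(gene_list)
    by_id = {g.gene_id: g for g in gene_list}
    cov = {
        g.gene_id: {
            "sense": np.zeros(g.exonic_length),
            "antisense": np.zeros(g.exonic_length),
        }
        for g in gene_list
    }
    for a in _filter_alignments(alignments, unique_only, primary_only):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(a.start, a.end)}
        if len(hits) != 1:
            continue
        gid = hits.pop()
        gene = by_id[gid]
        cls = assign_read_strand(a.strand, gene.strand, orientation)
        arr = cov[gid][cls]
        for t0, t1 in gene.genomic_to_transcript_blocks(a.start, a.end):
            arr[t0:t1] += 1
    return cov


def _bin_sums(arr: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, edges[:-1])


def gene_body_coverage_profile(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    n_bins: int = 100,
    strand_filter: str = "sense",
    orientation: str = "reverse",
) -> np.ndarray:
    """Mean normalised coverage along the spliced gene body, 5'->3'.

    Per eligible gene (exonic length >= ``n_bins`` and >= 1 contributing
    read) coverage is averaged within equal-fraction bins and divided by
    the gene's mean coverage, so a uniformly covered gene is flat at 1.0;
    the profile is the mean over genes.
    """
    if strand_filter not in ("sense", "antisense", "both"):
        raise ValueError(f"unknown strand_filter {strand_filter!r}")
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    cov = _per_gene_coverage(alignments, gene_list, orientation)
    profiles = []
    for gene in gene_list:
        if gene.exonic_length < n_bins:
            continue
        c = cov[gene.gene_id]
        arr = (
            c["sense"] + c["antisense"]
            if strand_filter == "both"
            else c[strand_filter]
        )
        mean_cov = arr.mean()
        if mean_cov == 0:
            continue
        edges = equal_fraction_edges(len(arr), n_bins)
        binned = _bin_sums(arr, edges) / np.diff(edges)
        profiles.append(binned / mean_cov)
    if not profiles:
        raise ValueError("no eligible gene (length >= n_bins with coverage)")
    return np.mean(profiles, axis=0)


def antisense_fraction_profile(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    n_bins: int = 100,
    orientation: str = "reverse",
) -> np.ndarray:
    """Percent antisense coverage per gene-body bin, pooled over genes.

    Per bin: ``100 * antisense / (sense + antisense)`` with coverage summed
    over all eligible genes; bins with zero total coverage are NaN.
    """
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    cov = _per_gene_coverage(alignments, gene_list, orientation)
    pooled_s = np.zeros(n_bins)
    pooled_a = np.zeros(n_bins)
    any_gene = False
    for gene in gene_list:
        if gene.exonic_length < n_bins:
            continue
        c = cov[gene.gene_id]
        if c["sense"].sum() + c["antisense"].sum() == 0:
            continue
        any_gene = True
        edges = equal_fraction_edges(gene.exonic_length, n_bins)
        widths = np.diff(edges)
        pooled_s += _bin_sums(c["sense"], edges) / widths
        pooled_a += _bin_sums(c["antisense"], edges) / widths
    if not any_gene:
        raise ValueError("no eligible gene with coverage")
    total = pooled_s + pooled_a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * pooled_a / total
    out[total == 0] = np.nan
    return out
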