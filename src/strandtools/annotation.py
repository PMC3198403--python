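"""Annotation-derived assets: gene models, the intron database, non-coding
regions (NCRs) and annotation-based sequence profiles.

These are the run-independent ("prepare once per genome") computations: they
depend only on the genome sequence and its annotation, never on reads.

A *gene model* here is the union of exons of one representative transcript
per gene (the longest isoform by exonic length, by default), so each gene
contributes a single, unambiguous exon chain.  Introns are the gaps between
consecutive exons of that chain, indexed 1-based in transcript (5'->3')
orientation.  NCRs are the genomic intervals whose every base lies at least
``min_distance`` (default 5 kb) from any annotated exon; they are used to
estimate the background read density of a sequencing run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "IntronRecord",
    "NcrInterval",
    "load_annotation",
    "build_intron_db",
    "derive_ncrs",
    "sequence_composition_profile",
    "equal_fraction_edges",
    "introns_to_bed",
    "ncrs_to_bed",
]


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """One gene as a stranded chain of non-overlapping exons.

    ``exons`` are stored sorted by genomic start; overlapping input exons
    are merged on construction.  ``exonic_length`` is the summed exon
    length L_g used for RPKM and for the Poisson rate offset of the
    expression test.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
        merged = _merge_intervals([(e.start, e.end) for e in self.exons])
        self.exons = [
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged
        ]

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    # -- spliced (transcript) coordinate machinery -------------------------

    @property
    def _exon_offsets(self) -> list[int]:
        """Cumulative spliced offset of each exon's genomic start (+ strand)."""
        offs, acc = [], 0
        for ex in self.exons:
            offs.append(acc)
            acc += ex.length
        return offs

    def genomic_to_transcript_blocks(
        self, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Map a genomic interval to half-open ranges of spliced transcript
        coordinates (5'->3' of the transcript), intersected with the exons.
        """
        L = self.exonic_length
        blocks: list[tuple[int, int]] = []
        for ex, off in zip(self.exons, self._exon_offsets):
            lo = max(start, ex.start)
            hi = min(end, ex.end)
            if lo < hi:
                t0 = off + (lo - ex.start)
                t1 = off + (hi - ex.start)
                if self.strand == "-":
                    t0, t1 = L - t1, L - t0
                blocks.append((t0, t1))
        return sorted(blocks)

    def exonic_overlap(self, start: int, end: int) -> int:
        """Number of exonic bases covered by the genomic interval."""
        return sum(t1 - t0 for t0, t1 in self.genomic_to_transcript_blocks(start, end))

    def spliced_sequence(self, genome: Mapping[str, object]) -> str:
        """The mature transcript sequence, reverse-complemented on '-'.

        ``genome`` is any mapping of chromosome name to a sliceable
        sequence (a :class:`pyfaidx.Fasta` or a plain dict of strings).
        """
        if self.chrom not in genome:
            raise KeyError(f"gene {self.gene_id}: chromosome {self.chrom!r} "
                           "absent from genome")
        chrom_seq = genome[self.chrom]
        seq = "".join(str(chrom_seq[e.start:e.end]) for e in self.exons).upper()
        if self.strand == "-":
            from Bio.Seq import Seq

            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a gene model, indexed 5'->3' in transcript orientation."""

    gene_id: str
    intron_index: int  # 1-based
    interval: GenomicInterval

    @property
    def name(self) -> str:
        return f"{self.gene_id}.intron_{self.intron_index}"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class NcrInterval:
    """A non-coding region: every base >= min_distance from any exon."""

    interval: GenomicInterval

    @property
    def name(self) -> str:
        iv = self.interval
        return f"NCR_{iv.chrom}_{iv.start}_{iv.end}"

    @property
    def length(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(
    path: str | Path,
    dialect: str | None = None,
    isoform_rule: str = "longest",
) -> dict[str, GeneModel]:
    """Parse a GFF3 or GTF file into one :class:`GeneModel` per gene.

    Parameters
    ----------
    path
        Annotation file (GFF3 or GTF; plain text or gzip).
    dialect
        ``"gff3"``, ``"gtf"`` or ``None`` to autodetect from the extension.
    isoform_rule
        ``"longest"`` (default): the representative model is the exon chain
        of the transcript with the largest exonic length.  ``"union"``: the
        exon union over all isoforms.

    Returns
    -------
    dict mapping gene_id -> GeneModel.
    """
    import gffutils

    path = str(path)
    if dialect is None:
        low = path.lower().removesuffix(".gz")
        dialect = "gtf" if low.endswith(".gtf") else "gff3"
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if isoform_rule not in ("longest", "union"):
        raise ValueError(f"unknown isoform rule {isoform_rule!r}")

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"failed to parse annotation {path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    seen_exons = 0
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        # transcripts (mRNA in GFF3, inferred 'transcript' in GTF)
        transcripts = list(
            db.children(gene, level=1, featuretype=("mRNA", "transcript"))
        )
        per_tx_exons: list[list[gffutils.Feature]] = []
        if transcripts:
            for tx in transcripts:
                exs = list(db.children(tx, featuretype="exon"))
                if exs:
                    per_tx_exons.append(exs)
        else:
            exs = list(db.children(gene, featuretype="exon"))
            if exs:
                per_tx_exons.append(exs)
        if not per_tx_exons:
            continue

        if isoform_rule == "union":
            chosen = [e for exs in per_tx_exons for e in exs]
        else:
            chosen = max(
                per_tx_exons, key=lambda exs: sum(e.end - e.start + 1 for e in exs)
            )
        seen_exons += len(chosen)
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, gene.strand) for e in chosen
        ]
        genes[gene_id] = GeneModel(gene_id, gene.seqid, gene.strand, exons)

    # orphan exons (no gene ancestry) indicate a broken annotation
    for exon in db.features_of_type("exon"):
        if not any(True for _ in db.parents(exon)):
            raise ValueError(
                f"exon {exon.seqid}:{exon.start}-{exon.end} has no parent feature"
            )
    return genes


def build_intron_db(genes: Mapping[str, GeneModel] | Iterable[GeneModel]) -> list[IntronRecord]:
    """Gaps between consecutive exons of each gene model.

    A gene with k exons contributes k-1 introns; ``intron_index`` counts
    5'->3' along the transcript, i.e. in reversed genomic order for
    '-'-strand genes.  Single-exon genes contribute nothing.
    """
    if isinstance(genes, Mapping):
        genes = genes.values()
    records: list[IntronRecord] = []
    for gene in genes:
        gaps = [
            (a.end, b.start)
            for a, b in zip(gene.exons, gene.exons[1:])
            if b.start > a.end
        ]
        if gene.strand == "-":
            gaps = gaps[::-1]
        for i, (s, e) in enumerate(gaps, start=1):
            records.append(
                IntronRecord(
                    gene.gene_id, i, GenomicInterval(gene.chrom, s, e, gene.strand)
                )
            )
    return records


def derive_ncrs(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    chrom_sizes: Mapping[str, int],
    min_distance: int = 5000,
    pad: str = "exons",
) -> list[NcrInterval]:
    """Non-coding regions: the complement of the annotation padded by
    ``min_distance`` on both sides.

    ``pad="exons"`` pads every exon (the operational definition used for
    background estimation); ``pad="span"`` pads whole transcript spans, a
    stricter alternative.
    """
    if pad not in ("exons", "span"):
        raise ValueError(f"unknown pad mode {pad!r}")
    if isinstance(genes, Mapping):
        genes = list(genes.values())
    else:
        genes = list(genes)

    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for gene in genes:
        if gene.chrom not in chrom_sizes:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        size = chrom_sizes[gene.chrom]
        regions = gene.exons if pad == "exons" else [gene.span]
        for reg in regions:
            if reg.end > size:
                raise ValueError(
                    f"gene {gene.gene_id}: exon ends at {reg.end} beyond "
                    f"chromosome {gene.chrom} length {size}"
                )
            by_chrom[gene.chrom].append(
                (max(0, reg.start - min_distance), min(size, reg.end + min_distance))
            )

    ncrs: list[NcrInterval] = []
    for chrom, size in chrom_sizes.items():
        blocked = _merge_intervals(by_chrom.get(chrom, []))
        cursor = 0
        for s, e in blocked:
            if s > cursor:
                ncrs.append(NcrInterval(GenomicInterval(chrom, cursor, s, ".")))
            cursor = max(cursor, e)
        if cursor < size:
            ncrs.append(NcrInterval(GenomicInterval(chrom, cursor, size, ".")))
    return ncrs


# ---------------------------------------------------------------------------
# sequence profiles
# ---------------------------------------------------------------------------

def equal_fraction_edges(length: int, n_bins: int) -> np.ndarray:
    """Integer bin edges splitting ``[0, length)`` into ``n_bins`` near-equal
    parts; every bin is non-empty when ``length >= n_bins``."""
    if length < n_bins:
        raise ValueError(f"length {length} < n_bins {n_bins}")
    return np.floor(np.linspace(0, length, n_bins + 1)).astype(int)


def sequence_composition_profile(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    genome: Mapping[str, object],
    bases: str | Iterable[str] = "GC",
    n_bins: int = 100,
) -> np.ndarray:
    """Metagene base-composition profile along the spliced transcript body.

    For each eligible gene (exonic length >= ``n_bins``) the mature
    transcript sequence is split into ``n_bins`` equal-fraction bins and
    the percentage of ``bases`` computed per bin; the profile is the mean
    over genes.  Used for GC content along the gene body and for %T
    diagnostics of antisense profiles.
    """
    base_set = {b.upper() for b in bases}
    if not base_set <= {"A", "C", "G", "T"}:
        raise ValueError(f"bases must be a subset of ACGT, got {sorted(base_set)}")
    if isinstance(genes, Mapping):
        genes = list(genes.values())
    else:
        genes = list(genes)

    profiles = []
    for gene in genes:
        if gene.exonic_length < n_bins:
            continue
        seq = gene.spliced_sequence(genome)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hit = np.zeros(arr.shape, dtype=float)
        for b in base_set:
            hit += arr == ord(b)
        edges = equal_fraction_edges(len(seq), n_bins)
        sums = np.add.reduceat(hit, edges[:-1])
        widths = np.diff(edges)
        profiles.append(100.0 * sums / widths)
    if not profiles:
        raise ValueError("no gene long enough for the requested number of bins")
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# BED6 export
# ---------------------------------------------------------------------------

def introns_to_bed(introns: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in introns:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t0\t{iv.strand}\n"
            )


def ncrs_to_bed(ncrs: Iterable[NcrInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ncrs:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t0\t.\n")
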