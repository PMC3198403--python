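"""Multiplex index validation and FASTQ demultiplexing.

Reads carry a short sample index at their 5' end (default: 5 variable
bases followed by one common T that equalises ligation efficiency).  Index
sets are designed with minimum pairwise edit distance >= 2 so that a read
with a single sequencing error in the index can still be assigned to a
unique sample.  Assignment uses Hamming distance over the fixed-length
prefix; a read is rescued at distance 1 only when the nearest index is
unique — ties are left unassigned, because distance 2 between indices does
not guarantee unambiguous one-error correction.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndexSet",
    "DemuxResult",
    "validate_index_set",
    "demultiplex",
    "summarize_index_balance",
    "read_fastq",
    "write_fastq",
]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class IndexSet:
    """A set of equal-length sample indices plus the read structure.

    ``n_common`` fixed bases (``common_base``) follow the variable index at
    the start of each read; they are checked for reporting but mismatches
    there never affect assignment.
    """

    indices: tuple[str, ...]
    n_common: int = 1
    common_base: str = "T"

    def __init__(self, indices: Sequence[str], n_common: int = 1, common_base: str = "T"):
        idx = tuple(s.upper() for s in indices)
        if len(idx) < 1:
            raise ValueError("need at least one index")
        k = len(idx[0])
        if any(len(s) != k for s in idx):
            raise ValueError("indices must all have the same length")
        for s in idx:
            if not set(s) <= _ACGT:
                raise ValueError(f"index {s!r} contains non-ACGT symbols")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate index sequences")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "n_common", int(n_common))
        object.__setattr__(self, "common_base", common_base.upper())

    @property
    def index_length(self) -> int:
        return len(self.indices[0])

    @property
    def prefix_length(self) -> int:
        """Total bases removed from an assigned read: index + common bases."""
        return self.index_length + self.n_common


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_index_set(index_set: IndexSet | Sequence[str]) -> dict:
    """Check an index set for error-correction capacity and base balance.

    Returns a dict with the minimum pairwise Hamming distance (substitutions
    only — indices have fixed length), the minimum pairwise Levenshtein
    distance (useful when designing new sets), a per-position base-frequency
    table, and ``valid`` = True iff the minimum Hamming distance is >= 2.
    """
    if not isinstance(index_set, IndexSet):
        index_set = IndexSet(index_set)
    idx = index_set.indices
    if len(idx) < 2:
        raise ValueError("validation requires at least two indices")

    import edlib

    min_ham = min(
        _hamming(a, b) for i, a in enumerate(idx) for b in idx[i + 1 :]
    )
    min_lev = min(
        edlib.align(a, b, task="distance")["editDistance"]
        for i, a in enumerate(idx)
        for b in idx[i + 1 :]
    )
    k = index_set.index_length
    freq = pd.DataFrame(
        [[sum(s[pos] == base for s in idx) / len(idx) for base in "ACGT"]
         for pos in range(k)],
        columns=list("ACGT"),
        index=pd.RangeIndex(k, name="position"),
    )
    return {
        "min_hamming": min_ham,
        "min_levenshtein": min_lev,
        "base_balance": freq,
        "valid": min_ham >= 2,
    }


@dataclass
class DemuxResult:
    """Per-index assignment tallies for one demultiplexing run (one lane)."""

    assigned: dict[str, int]
    exact: dict[str, int]
    rescued: dict[str, int]
    unassigned: int
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        """Fraction of *all* reads assigned to each index."""
        if self.total == 0:
            return {k: 0.0 for k in self.assigned}
        return {k: v / self.total for k, v in self.assigned.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "index": k,
                "reads": self.assigned[k],
                "exact": self.exact[k],
                "rescued": self.rescued[k],
                "fraction": self.fractions[k],
            }
            for k in self.assigned
        ]
        return pd.DataFrame(rows)


def _assign_codes(
    prefixes: np.ndarray, index_arr: np.ndarray, max_mismatch: int
) -> np.ndarray:
    """Vectorised nearest-index assignment.

    ``prefixes``: (n, k) uint8 array of read prefixes; ``index_arr``: (m, k).
    Returns an int array of index positions, -1 for unassigned (too far or
    tied at the minimal distance).
    """
    # (n, m) Hamming distances via broadcasting
    dist = (prefixes[:, None, :] != index_arr[None, :, :]).sum(axis=2)
    best = dist.min(axis=1)
    n_best = (dist == best[:, None]).sum(axis=1)
    choice = dist.argmin(axis=1)
    choice[(best > max_mismatch) | (n_best > 1)] = -1
    return choice


def demultiplex(
    reads: Iterable[tuple[str, str, str]] | str | Path,
    index_set: IndexSet,
    max_mismatch: int = 1,
    output_dir: str | Path | None = None,
    chunk_size: int = 100_000,
) -> tuple[dict[str, list[tuple[str, str, str]]] | None, DemuxResult]:
    """Assign reads to sample indices by their 5' prefix.

    Parameters
    ----------
    reads
        FASTQ path (gzip-transparent) or an iterable of
        ``(read_id, sequence, quality)`` tuples.
    index_set
        The expected indices and read structure.
    max_mismatch
        Maximum Hamming distance to the index for assignment (default 1).
    output_dir
        If given, per-index FASTQ files ``<index>.fastq`` are written there
        and the in-memory per-index read lists are not returned.

    Assigned reads are trimmed of the index and the common base(s).  Reads
    shorter than the prefix, reads beyond ``max_mismatch`` from every index
    and ties at the minimal distance are all left unassigned.
    """
    k = index_set.index_length
    prefix_len = index_set.prefix_length
    index_arr = np.frombuffer(
        "".join(index_set.indices).encode(), dtype=np.uint8
    ).reshape(len(index_set.indices), k).copy()

    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)

    assigned = {ix: 0 for ix in index_set.indices}
    exact = {ix: 0 for ix in index_set.indices}
    rescued = {ix: 0 for ix in index_set.indices}
    unassigned = 0
    total = 0

    collect: dict[str, list[tuple[str, str, str]]] | None
    writers = None
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        writers = {
            ix: open(output_dir / f"{ix}.fastq", "w") for ix in index_set.indices
        }
        collect = None
    else:
        collect = {ix: [] for ix in index_set.indices}

    def flush(chunk: list[tuple[str, str, str]]) -> None:
        nonlocal unassigned
        prefixes = np.frombuffer(
            "".join(r[1][:k] for r in chunk).encode(), dtype=np.uint8
        ).reshape(len(chunk), k)
        codes = _assign_codes(prefixes, index_arr, max_mismatch)
        dists = (prefixes != index_arr[codes]).sum(axis=1)
        for (rid, seq, qual), code, d in zip(chunk, codes, dists):
            if code < 0:
                unassigned += 1
                continue
            ix = index_set.indices[code]
            assigned[ix] += 1
            if d == 0:
                exact[ix] += 1
            else:
                rescued[ix] += 1
            trimmed = (rid, seq[prefix_len:], qual[prefix_len:])
            if writers is not None:
                fh = writers[ix]
                fh.write(f"@{rid}\n{trimmed[1]}\n+\n{trimmed[2]}\n")
            else:
                collect[ix].append(trimmed)

    chunk: list[tuple[str, str, str]] = []
    try:
        for rid, seq, qual in reads:
            total += 1
            if len(seq) < prefix_len:
                unassigned += 1
                continue
            chunk.append((rid, seq.upper(), qual))
            if len(chunk) >= chunk_size:
                flush(chunk)
                chunk = []
        if chunk:
            flush(chunk)
    finally:
        if writers is not None:
            for fh in writers.values():
                fh.close()

    result = DemuxResult(assigned, exact, rescued, unassigned, total)
    return collect, result


def summarize_index_balance(lanes: Sequence[DemuxResult]) -> pd.DataFrame:
    """Across-lane mean fraction and standard error per index.

    Lanes with zero total reads are excluded with a warning.  The standard
    error is the SEM of the within-lane fractions (0 for a single lane).
    """
    if len(lanes) == 0:
        raise ValueError("need at least one lane")
    usable = [ln for ln in lanes if ln.total > 0]
    if len(usable) < len(lanes):
        warnings.warn(
            f"excluded {len(lanes) - len(usable)} lane(s) with zero reads",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("all lanes empty")
    indices = list(usable[0].assigned)
    frac = np.array([[ln.fractions[ix] for ix in indices] for ln in usable])
    mean = frac.mean(axis=0)
    sem = (
        frac.std(axis=0, ddof=1) / np.sqrt(len(usable))
        if len(usable) > 1
        else np.zeros(len(indices))
    )
    return pd.DataFrame(
        {"index": indices, "mean_fraction": mean, "sem": sem}
    ).set_index("index")


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, gzip-transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.description, str(rec.seq), qual


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> int:
    """Write (read_id, sequence, quality) tuples as FASTQ; returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
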