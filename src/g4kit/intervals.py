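"""Genomic interval data model, set algebra, and BED/FASTA I/O.

All coordinates are BED-convention 0-based half-open ``[start, end)``.
Bookended intervals (``[0,10)`` and ``[10,20)``) merge into one.
``merge``, ``intersect_bp`` and ``jaccard`` ignore strand; strand-aware
logic lives in :mod:`g4kit.assoc`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "FormatError",
    "merge",
    "intersect_bp",
    "jaccard",
    "subtract",
    "complement",
    "read_bed",
    "write_bed",
    "Genome",
]


class FormatError(ValueError):
    """Raised for malformed records in interval or sequence inputs."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open genomic interval.

    Parameters
    ----------
    chrom : chromosome name.
    start : 0-based inclusive start (bp).
    end : exclusive end (bp); must satisfy ``start < end``.
    strand : one of ``+``, ``-``, ``.`` (default unstranded).
    score : optional real-valued score.
    name : optional record name.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalSet:
    """A named collection of intervals with cached merged length."""

    name: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __bool__(self) -> bool:  # empty sets are falsy but valid
        return bool(self.intervals)

    @property
    def merged_length(self) -> int:
        """Total bp covered after per-chromosome merging."""
        return sum(iv.width for iv in merge(self).intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        return out


def _merge_runs(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge sorted (start, end) pairs; bookended runs coalesce."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def merge(iset: IntervalSet) -> IntervalSet:
    """Merge overlapping/bookended intervals per chromosome.

    The result is sorted, pairwise disjoint, covers exactly the same
    bases, and is idempotent. Strand and scores are dropped.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in iset.intervals}):
        runs = [(iv.start, iv.end) for iv in iset.intervals if iv.chrom == chrom]
        merged.extend(GenomicInterval(chrom, s, e) for s, e in _merge_runs(runs))
    return IntervalSet(name=iset.name, intervals=merged)


def intersect_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Number of bases covered by both sets: ``|bases(a) & bases(b)|``."""
    total = 0
    bm = merge(b).by_chrom()
    for chrom, a_ivs in merge(a).by_chrom().items():
        b_ivs = bm.get(chrom, [])
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if lo < hi:
                total += hi - lo
            if a_ivs[i].end <= b_ivs[j].end:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Jaccard score: intersection bp over union bp of the merged sets.

    Returns 0.0 when the union is empty, by convention.
    """
    inter = intersect_bp(a, b)
    union = a.merged_length + b.merged_length - inter
    return inter / union if union else 0.0


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b``, as a merged set."""
    bm = merge(b).by_chrom()
    out: list[GenomicInterval] = []
    for chrom, a_ivs in merge(a).by_chrom().items():
        cuts = bm.get(chrom, [])
        for iv in a_ivs:
            pos = iv.start
            for c in cuts:
                if c.end <= pos or c.start >= iv.end:
                    continue
                if c.start > pos:
                    out.append(GenomicInterval(chrom, pos, c.start))
                pos = max(pos, c.end)
            if pos < iv.end:
                out.append(GenomicInterval(chrom, pos, iv.end))
    return IntervalSet(name=a.name, intervals=out)


def complement(iset: IntervalSet, chrom_lengths: dict[str, int]) -> IntervalSet:
    """Bases of each chromosome not covered by ``iset``."""
    whole = IntervalSet(
        intervals=[GenomicInterval(c, 0, n) for c, n in chrom_lengths.items()]
    )
    return subtract(whole, iset)


def overlaps_any(iv: GenomicInterval, iset: IntervalSet) -> bool:
    """True iff ``iv`` shares >= 1 bp with any interval of ``iset``."""
    for other in iset.intervals:
        if iv.overlaps(other):
            return True
    return False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike, name: str | None = None) -> IntervalSet:
    """Read a BED3/BED6 file (tab-separated, no header).

    ``track``/``browser``/``#`` lines are skipped. Coordinates are kept
    0-based half-open as in the file. Column 5 is parsed as ``score``
    when numeric, column 4 as ``name``, column 6 as strand.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            rec_name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, score, rec_name)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(name=name or os.path.basename(str(path)), intervals=intervals)


def write_bed(iset: IntervalSet | Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED6 (0-based half-open); scores rendered with 4 decimals."""
    ivs = iset.intervals if isinstance(iset, IntervalSet) else list(iset)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            score = f"{iv.score:.4f}" if iv.score is not None else "."
            name = iv.name if iv.name is not None else f"iv{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


class Genome:
    """Random-access genome sequence backed by pyfaidx.

    Falls back to an in-memory dict when given one (tests and the
    simulator pass plain ``{chrom: sequence}`` mappings).
    """

    def __init__(self, source: str | os.PathLike | dict[str, str]):
        if isinstance(source, dict):
            self._seqs = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._seqs = None

    def keys(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: self.length(c) for c in self.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence for [start, end), clipped at bounds."""
        start = max(0, start)
        end = min(self.length(chrom), end)
        if start >= end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()
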