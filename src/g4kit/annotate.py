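"""Genomic feature annotation of G4 sites.

Builds a genome-tiling feature map from gene models, assigns each G4 to
one feature class by its midpoint, computes the per-class G4 density
``D_k = 1000 * sum_i W_i / L_k`` (bp per kb, BPKB) and the signed TSS
distance profile.

Overlapping raw classes are resolved by a fixed precedence:
``upstream10kb > utr5 > utr3 > exon > intron > downstream2kb >
intergenic``; after resolution the seven classes partition each
chromosome.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .evidence import EvidenceGroups
from .intervals import FormatError, GenomicInterval, IntervalSet, merge, subtract

__all__ = [
    "GeneModel",
    "FeatureMap",
    "FEATURE_CLASSES",
    "build_feature_map",
    "assign_region",
    "density_table",
    "tss_profile",
    "read_gene_table",
    "write_gene_table",
]

FEATURE_CLASSES = (
    "upstream10kb",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream2kb",
    "intergenic",
)

UPSTREAM_BP = 10_000
DOWNSTREAM_BP = 2_000


@dataclass(frozen=True)
class GeneModel:
    """A gene with one canonical transcript.

    ``exons`` are sorted, non-overlapping (start, end) blocks within the
    transcript bounds; when empty, the whole transcript span is treated
    as a single exon. ``cds_start``/``cds_end`` delimit the coding span
    used to derive the UTRs.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise FormatError(f"{self.gene_id}: tx_start >= tx_end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: gene strand must be + or -")
        prev = self.tx_start
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e or s < prev:
                raise FormatError(f"{self.gene_id}: malformed exon blocks")
            prev = e

    @property
    def tss(self) -> int:
        """TSS coordinate: tx_start for '+', tx_end for '-' genes."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def exon_blocks(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.exons else ((self.tx_start, self.tx_end),)

    def upstream_window(self, size: int = UPSTREAM_BP) -> GenomicInterval | None:
        """Strand-aware window 5' of the TSS, clipped at 0; None if empty."""
        if self.strand == "+":
            s, e = max(0, self.tx_start - size), self.tx_start
        else:
            s, e = self.tx_end, self.tx_end + size
        return GenomicInterval(self.chrom, s, e, self.strand) if s < e else None

    def downstream_window(self, size: int = DOWNSTREAM_BP) -> GenomicInterval | None:
        if self.strand == "+":
            s, e = self.tx_end, self.tx_end + size
        else:
            s, e = max(0, self.tx_start - size), self.tx_start
        return GenomicInterval(self.chrom, s, e, self.strand) if s < e else None

    def body_window(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass
class FeatureMap:
    """Precedence-resolved feature classes tiling the genome."""

    classes: dict[str, IntervalSet]
    chrom_lengths: dict[str, int]
    _index: dict[str, tuple[list[int], list[int], list[str]]] = field(
        default_factory=dict, repr=False
    )

    @property
    def lengths(self) -> dict[str, int]:
        """Merged length L_k of each class."""
        return {k: s.merged_length for k, s in self.classes.items()}

    def _build_index(self) -> None:
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for label, iset in self.classes.items():
            for iv in iset.intervals:
                per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, label))
        for chrom, triples in per_chrom.items():
            triples.sort()
            self._index[chrom] = (
                [t[0] for t in triples],
                [t[1] for t in triples],
                [t[2] for t in triples],
            )

    def class_at(self, chrom: str, pos: int) -> str | None:
        """Feature class containing base ``pos`` (None off-chromosome)."""
        if not self._index:
            self._build_index()
        if chrom not in self._index:
            return None
        starts, ends, labels = self._index[chrom]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return None


def _raw_class_sets(genes: list[GeneModel], chrom_lengths: dict[str, int]) -> dict[str, list[GenomicInterval]]:
    raw: dict[str, list[GenomicInterval]] = {k: [] for k in FEATURE_CLASSES[:-1]}
    for g in genes:
        clen = chrom_lengths[g.chrom]
        up = g.upstream_window()
        if up is not None:
            s, e = up.start, min(up.end, clen)
            if s < e:
                raw["upstream10kb"].append(GenomicInterval(g.chrom, s, e))
        down = g.downstream_window()
        if down is not None:
            s, e = down.start, min(down.end, clen)
            if s < e:
                raw["downstream2kb"].append(GenomicInterval(g.chrom, s, e))
        exons = g.exon_blocks
        raw["exon"].extend(GenomicInterval(g.chrom, s, e) for s, e in exons)
        # introns: transcript span minus exons
        pos = g.tx_start
        for s, e in exons:
            if s > pos:
                raw["intron"].append(GenomicInterval(g.chrom, pos, s))
            pos = e
        if pos < g.tx_end:
            raw["intron"].append(GenomicInterval(g.chrom, pos, g.tx_end))
        # UTRs from the coding span, restricted to exon bases
        if g.cds_start is not None and g.cds_end is not None and g.cds_start < g.cds_end:
            left = (g.tx_start, g.cds_start)  # 5' for '+', 3' for '-'
            right = (g.cds_end, g.tx_end)
            five, three = (left, right) if g.strand == "+" else (right, left)
            for (s, e), label in ((five, "utr5"), (three, "utr3")):
                for xs, xe in exons:
                    lo, hi = max(s, xs), min(e, xe)
                    if lo < hi:
                        raw[label].append(GenomicInterval(g.chrom, lo, hi))
    return raw


def build_feature_map(genes: list[GeneModel], chrom_lengths: dict[str, int]) -> FeatureMap:
    """Build the precedence-resolved feature map.

    Raises a format error when a gene (or its 2-kb downstream window)
    extends past its chromosome end.
    """
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise FormatError(f"{g.gene_id}: unknown chromosome {g.chrom}")
        if g.tx_end > chrom_lengths[g.chrom]:
            raise FormatError(f"{g.gene_id}: transcript beyond chromosome end")
    raw = _raw_class_sets(genes, chrom_lengths)
    whole = IntervalSet(
        intervals=[GenomicInterval(c, 0, n) for c, n in chrom_lengths.items()]
    )
    claimed = IntervalSet(intervals=[])
    resolved: dict[str, IntervalSet] = {}
    for label in FEATURE_CLASSES[:-1]:
        cls = merge(IntervalSet(label, raw[label]))
        own = subtract(cls, claimed)
        own.name = label
        resolved[label] = own
        claimed = merge(IntervalSet(intervals=claimed.intervals + own.intervals))
    intergenic = subtract(whole, claimed)
    intergenic.name = "intergenic"
    resolved["intergenic"] = intergenic
    return FeatureMap(classes=resolved, chrom_lengths=dict(chrom_lengths))


def assign_region(g4: GenomicInterval, fmap: FeatureMap) -> str:
    """Feature class containing the G4 midpoint."""
    label = fmap.class_at(g4.chrom, g4.midpoint)
    if label is None:
        raise FormatError(f"G4 {g4.chrom}:{g4.start}-{g4.end} outside known chromosomes")
    return label


def region_fractions(groups: EvidenceGroups, fmap: FeatureMap) -> pd.DataFrame:
    """Per-group fraction of G4s whose midpoint falls in each class."""
    rows = []
    for gname, iset in groups.as_dict().items():
        counts = {k: 0 for k in FEATURE_CLASSES}
        for iv in iset.intervals:
            counts[assign_region(iv, fmap)] += 1
        n = max(1, len(iset))
        for k in FEATURE_CLASSES:
            rows.append(
                {"group": gname, "class": k, "count": counts[k], "fraction": counts[k] / n}
            )
    return pd.DataFrame(rows)


def density_table(groups: EvidenceGroups, fmap: FeatureMap) -> pd.DataFrame:
    """BPKB density per (group, class).

    ``W_i`` is the width of the intersection of G4 *i* with the class (a
    boundary-spanning G4 contributes its overlap to each class it
    touches); ``D_k = 1000 * sum W_i / L_k``. Classes of zero length get
    a blank (NaN) density, not zero.
    """
    class_chrom: dict[str, dict[str, list[GenomicInterval]]] = {
        k: s.by_chrom() for k, s in fmap.classes.items()
    }
    lengths = fmap.lengths
    rows = []
    for gname, iset in groups.as_dict().items():
        for k in FEATURE_CLASSES:
            w_total = 0
            for iv in iset.intervals:
                for civ in class_chrom[k].get(iv.chrom, []):
                    if civ.start >= iv.end:
                        break
                    w_total += iv.overlap_bp(civ)
            lk = lengths[k]
            rows.append(
                {
                    "group": gname,
                    "class": k,
                    "overlap_bp": w_total,
                    "class_length": lk,
                    "bpkb": 1000.0 * w_total / lk if lk > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def tss_profile(
    groups: EvidenceGroups,
    genes: list[GeneModel],
    window: tuple[int, int] = (-10_000, 500),
    bin_size: int = 500,
) -> pd.DataFrame:
    """Histogram of G4 midpoint distances to the nearest TSS, per group.

    Distances are signed in gene orientation (negative = upstream of the
    TSS). ``bin_size`` must divide the window evenly. The histogram
    total equals the number of G4s whose nearest-TSS distance falls in
    the window.
    """
    lo, hi = window
    if (hi - lo) % bin_size != 0:
        raise ValueError("bin_size must divide the window evenly")
    nbins = (hi - lo) // bin_size
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand))
    for lst in tss_by_chrom.values():
        lst.sort()

    rows = []
    for gname, iset in groups.as_dict().items():
        counts = [0] * nbins
        for iv in iset.intervals:
            sites = tss_by_chrom.get(iv.chrom)
            if not sites:
                continue
            mid = iv.midpoint
            i = bisect_right([p for p, _ in sites], mid)
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(sites):
                    pos, strand = sites[j]
                    d = mid - pos if strand == "+" else pos - mid
                    if best is None or abs(d) < abs(best):
                        best = d
            if best is None or not (lo <= best <= hi):
                continue
            b = min((best - lo) // bin_size, nbins - 1)
            counts[b] += 1
        for b in range(nbins):
            rows.append(
                {
                    "group": gname,
                    "bin_start": lo + b * bin_size,
                    "bin_end": lo + (b + 1) * bin_size,
                    "count": counts[b],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene table I/O
# ---------------------------------------------------------------------------

def read_gene_table(path: str | os.PathLike) -> list[GeneModel]:
    """Read a gene TSV with header columns gene_id, chrom, strand,
    tx_start, tx_end, cds_start, cds_end and optional comma-separated
    exon_starts/exon_ends. Coordinates 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    genes = []
    for rec in df.itertuples(index=False):
        exons: tuple[tuple[int, int], ...] = ()
        if hasattr(rec, "exon_starts") and isinstance(rec.exon_starts, str):
            starts = [int(x) for x in rec.exon_starts.rstrip(",").split(",")]
            ends = [int(x) for x in rec.exon_ends.rstrip(",").split(",")]
            exons = tuple(zip(starts, ends))
        genes.append(
            GeneModel(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                strand=rec.strand,
                tx_start=int(rec.tx_start),
                tx_end=int(rec.tx_end),
                cds_start=int(rec.cds_start) if pd.notna(rec.cds_start) else None,
                cds_end=int(rec.cds_end) if pd.notna(rec.cds_end) else None,
                exons=exons,
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "cds_start": g.cds_start if g.cds_start is not None else "",
                "cds_end": g.cds_end if g.cds_end is not None else "",
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
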