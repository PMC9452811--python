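"""Overlap of G4 groups with epigenomic tracks, TF peak sets, and CpG
methylation state analysis.

Methylation follows the bedMethyl-style convention: one CpG per row with
a read coverage and a beta value (proportion methylated). Hypomethylated
means beta <= 0.1, hypermethylated beta >= 0.9 (both thresholds
inclusive); everything else is intermediate. Only CpG context is
analysed; CHG/CHH rows are dropped at read time.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass

import pandas as pd

from .evidence import EvidenceGroups
from .intervals import IntervalSet, jaccard, merge

__all__ = [
    "MethylRecord",
    "MethylStateSummary",
    "overlap_ratio",
    "tf_jaccard_matrix",
    "filter_methyl",
    "methyl_state",
    "methyl_by_group",
    "telomere_profile",
    "read_methyl",
]

HYPO_MAX = 0.1
HYPER_MIN = 0.9
JACCARD_FLAG_THRESHOLD = 0.1


@dataclass(frozen=True)
class MethylRecord:
    chrom: str
    pos: int  # 0-based CpG start
    coverage: int
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta {self.beta} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.coverage < 0:
            raise ValueError(f"negative coverage at {self.chrom}:{self.pos}")


@dataclass
class MethylStateSummary:
    """Per-group CpG counts, state fractions and CpG density (per kb)."""

    table: pd.DataFrame  # columns: group, n_cpg, frac_hypo, frac_hyper,
    #          frac_intermediate, cpg_density


def overlap_ratio(group: IntervalSet, track: IntervalSet) -> float:
    """Fraction of group members with >= 1 bp overlap with the track."""
    if not group.intervals:
        raise ValueError(f"group {group.name!r} is empty")
    by_chrom = merge(track).by_chrom()
    hits = 0
    for iv in group.intervals:
        for t in by_chrom.get(iv.chrom, []):
            if t.start >= iv.end:
                break
            if t.end > iv.start:
                hits += 1
                break
    return hits / len(group.intervals)


def tf_jaccard_matrix(
    groups: EvidenceGroups, tf_sets: dict[str, IntervalSet]
) -> pd.DataFrame:
    """Jaccard score per (TF, G4 group), with a flag for scores > 0.1."""
    rows = []
    for tf_name, tf_set in tf_sets.items():
        row: dict[str, object] = {"tf": tf_name}
        for gname, gset in groups.as_dict().items():
            row[gname] = jaccard(tf_set, gset)
        row["above_threshold"] = any(
            row[g] > JACCARD_FLAG_THRESHOLD for g in groups.as_dict()
        )
        rows.append(row)
    return pd.DataFrame(rows)


def filter_methyl(records: list[MethylRecord], min_cov: int = 10) -> list[MethylRecord]:
    """Keep CpGs with coverage >= min_cov (boundary inclusive)."""
    return [r for r in records if r.coverage >= min_cov]


def methyl_state(beta: float) -> str:
    """Bin a beta value: hypo (<= 0.1), hyper (>= 0.9), else intermediate."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0, 1]")
    if beta <= HYPO_MAX:
        return "hypo"
    if beta >= HYPER_MIN:
        return "hyper"
    return "intermediate"


def _covers(pos: int, starts: list[int], ends: list[int]) -> bool:
    i = bisect_right(starts, pos) - 1
    return i >= 0 and pos < ends[i]


def methyl_by_group(
    records: list[MethylRecord],
    groups: EvidenceGroups,
    unique_assignment: bool = False,
) -> MethylStateSummary:
    """Per-group methylation state fractions and CpG density.

    By default a CpG covered by intervals of several groups counts in
    each of them; with ``unique_assignment`` it counts only in the
    highest-priority group (II > I > III). Density is CpGs per kb of the
    group's merged length.
    """
    group_order = ["G4-II", "G4-I", "G4-III"]
    indexes: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
    merged_len: dict[str, int] = {}
    for gname, iset in groups.as_dict().items():
        m = merge(iset)
        merged_len[gname] = sum(iv.width for iv in m.intervals)
        idx: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in m.by_chrom().items():
            idx[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])
        indexes[gname] = idx

    counts = {g: {"hypo": 0, "hyper": 0, "intermediate": 0} for g in group_order}
    for rec in records:
        state = methyl_state(rec.beta)
        for gname in group_order:
            idx = indexes[gname].get(rec.chrom)
            if idx and _covers(rec.pos, *idx):
                counts[gname][state] += 1
                if unique_assignment:
                    break

    rows = []
    for gname in ["G4-I", "G4-II", "G4-III"]:
        c = counts[gname]
        n = c["hypo"] + c["hyper"] + c["intermediate"]
        denom = max(n, 1)
        rows.append(
            {
                "group": gname,
                "n_cpg": n,
                "frac_hypo": c["hypo"] / denom,
                "frac_hyper": c["hyper"] / denom,
                "frac_intermediate": c["intermediate"] / denom,
                "cpg_density": 1000.0 * n / merged_len[gname] if merged_len[gname] else float("nan"),
            }
        )
    return MethylStateSummary(table=pd.DataFrame(rows))


def telomere_profile(
    records: list[MethylRecord],
    groups: EvidenceGroups,
    chrom_lengths: dict[str, int],
    max_dist: int = 60_000,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Hypo/hyper fractions near chromosome ends.

    Each CpG's distance to the nearest chromosome end is
    ``min(pos, length - pos)``; CpGs with distance <= max_dist are
    binned (half-open bins, final bin closed so distance == max_dist is
    kept). Fractions are reported for all CpGs and for CpGs covered by
    any G4 interval of any group.
    """
    g4_all = merge(
        IntervalSet(
            intervals=groups.g4_I.intervals
            + groups.g4_II.intervals
            + groups.g4_III.intervals
        )
    )
    g4_idx = {
        chrom: ([iv.start for iv in ivs], [iv.end for iv in ivs])
        for chrom, ivs in g4_all.by_chrom().items()
    }
    nbins = max_dist // bin_size
    stats = [
        {"all_n": 0, "all_hypo": 0, "all_hyper": 0, "g4_n": 0, "g4_hypo": 0, "g4_hyper": 0}
        for _ in range(nbins)
    ]
    for rec in records:
        if rec.chrom not in chrom_lengths:
            continue
        dist = min(rec.pos, chrom_lengths[rec.chrom] - rec.pos)
        if dist > max_dist:
            continue
        b = min(dist // bin_size, nbins - 1)  # closed final bin
        state = methyl_state(rec.beta)
        stats[b]["all_n"] += 1
        if state == "hypo":
            stats[b]["all_hypo"] += 1
        elif state == "hyper":
            stats[b]["all_hyper"] += 1
        idx = g4_idx.get(rec.chrom)
        if idx and _covers(rec.pos, *idx):
            stats[b]["g4_n"] += 1
            if state == "hypo":
                stats[b]["g4_hypo"] += 1
            elif state == "hyper":
                stats[b]["g4_hyper"] += 1

    rows = []
    for b, s in enumerate(stats):
        rows.append(
            {
                "bin_start": b * bin_size,
                "bin_end": (b + 1) * bin_size,
                "n_all": s["all_n"],
                "frac_hypo_all": s["all_hypo"] / s["all_n"] if s["all_n"] else float("nan"),
                "frac_hyper_all": s["all_hyper"] / s["all_n"] if s["all_n"] else float("nan"),
                "n_g4": s["g4_n"],
                "frac_hypo_g4": s["g4_hypo"] / s["g4_n"] if s["g4_n"] else float("nan"),
                "frac_hyper_g4": s["g4_hyper"] / s["g4_n"] if s["g4_n"] else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def read_methyl(path: str | os.PathLike, percent: bool = False) -> list[MethylRecord]:
    """Read a bedMethyl-like TSV: chrom, start, end, coverage, beta.

    With ``percent`` the 5th column is a percentage and is divided by
    100. A header row starting with 'chrom' is tolerated.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "chrom\t")):
                continue
            f = line.split("\t")
            beta = float(f[4])
            if percent:
                beta /= 100.0
            records.append(MethylRecord(f[0], int(f[1]), int(f[3]), beta))
    return records
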