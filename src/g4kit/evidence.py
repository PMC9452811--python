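"""Partition G4 evidence into tiers.

G4-I: ChIP peaks overlapping no prediction (peak-shaped, unstranded).
G4-II: predictions with >= 1 bp overlap with >= 1 peak (prediction
coordinates and strand retained).
G4-III: the remaining predictions.

The minimum overlap is 1 bp and prediction strand is ignored (peaks are
unstranded). A peak overlapping any prediction contributes nothing to
G4-I, even its non-overlapping portion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hunter import G4Prediction
from .intervals import GenomicInterval, IntervalSet

__all__ = ["EvidenceGroups", "classify", "group_summary"]

GROUP_NAMES = ("G4-I", "G4-II", "G4-III")


@dataclass
class EvidenceGroups:
    g4_I: IntervalSet
    g4_II: IntervalSet
    g4_III: IntervalSet
    n_supporting_peaks: int = 0

    def as_dict(self) -> dict[str, IntervalSet]:
        return {"G4-I": self.g4_I, "G4-II": self.g4_II, "G4-III": self.g4_III}


def classify(predictions: list[G4Prediction], peaks: IntervalSet) -> EvidenceGroups:
    """Split predictions and peaks into the three evidence tiers."""
    peak_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, pk in enumerate(peaks.intervals):
        peak_by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end, idx))
    for lst in peak_by_chrom.values():
        lst.sort()

    g4_ii: list[GenomicInterval] = []
    g4_iii: list[GenomicInterval] = []
    supporting: set[int] = set()
    for pred in predictions:
        iv = pred.interval
        hit = False
        for s, e, idx in peak_by_chrom.get(iv.chrom, []):
            if s >= iv.end:
                break
            if e > iv.start:
                hit = True
                supporting.add(idx)
        if hit:
            g4_ii.append(iv)
        else:
            g4_iii.append(iv)

    g4_i = [
        GenomicInterval(pk.chrom, pk.start, pk.end, ".", pk.score, pk.name)
        for idx, pk in enumerate(peaks.intervals)
        if idx not in supporting
    ]
    return EvidenceGroups(
        g4_I=IntervalSet("G4-I", g4_i),
        g4_II=IntervalSet("G4-II", g4_ii),
        g4_III=IntervalSet("G4-III", g4_iii),
        n_supporting_peaks=len(supporting),
    )


def group_summary(groups: EvidenceGroups) -> pd.DataFrame:
    """Per-group count, total bp and width quartiles."""
    rows = []
    for name, iset in groups.as_dict().items():
        widths = np.array([iv.width for iv in iset.intervals])
        if widths.size:
            q1, q2, q3 = np.percentile(widths, [25, 50, 75])
        else:
            q1 = q2 = q3 = 0.0
        rows.append(
            {
                "group": name,
                "count": len(iset),
                "total_bp": int(widths.sum()),
                "width_q1": float(q1),
                "width_median": float(q2),
                "width_q3": float(q3),
            }
        )
    return pd.DataFrame(rows)
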