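"""Sequence-based G4 prediction by run-length G/C scoring.

Each guanine scores ``+min(run, 4)`` where *run* is the length of the
maximal G-run containing it; cytosines score the negative analogue;
A/T/N score 0 (N breaks runs). A window of ``w`` bp slides over the
sequence; windows whose mean base score reaches ``|mean| >= T`` qualify,
and overlapping/bookended qualifying windows of the same sign merge into
a single prediction whose score is recomputed over the merged span.
Positive scores mean a plus-strand (G-rich) candidate, negative scores a
minus-strand one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, Genome

__all__ = ["G4HunterParams", "G4Prediction", "base_scores", "predict_g4", "predict_genome"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class G4HunterParams:
    """Scoring parameters: odd window width ``w`` (bp) and threshold ``T``."""

    window: int = 25
    threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 5, got {self.window}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")


@dataclass(frozen=True)
class G4Prediction:
    """A merged qualifying region with its mean base score.

    ``sequence`` is always the plus-strand genomic subsequence; strand
    ``+``/``-`` follows the sign of ``mean_score``.
    """

    interval: GenomicInterval
    mean_score: float
    sequence: str = ""

    @property
    def strand(self) -> str:
        return self.interval.strand


def base_scores(seq: str) -> np.ndarray:
    """Per-base run-length scores for a DNA string.

    Gs in a maximal run of length r each score ``min(r, 4)``; Cs score
    ``-min(r, 4)``; A, T and N score 0.
    """
    s = seq.upper()
    n = len(s)
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    scores = np.zeros(n, dtype=np.int64)
    i = 0
    while i < n:
        base = s[i]
        j = i
        while j < n and s[j] == base:
            j += 1
        if base == "G":
            scores[i:j] = min(j - i, 4)
        elif base == "C":
            scores[i:j] = -min(j - i, 4)
        i = j
    return scores


def _qualifying_window_starts(scores: np.ndarray, w: int, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Start indices of windows with mean >= T (plus) or <= -T (minus)."""
    kernel = np.ones(w)
    sums = np.convolve(scores.astype(float), kernel, mode="valid")
    means = sums / w
    return np.flatnonzero(means >= threshold), np.flatnonzero(means <= -threshold)


def _merge_starts(starts: np.ndarray, w: int) -> list[tuple[int, int]]:
    """Merge overlapping/bookended windows given their start indices."""
    regions: list[tuple[int, int]] = []
    for s in starts:
        s = int(s)
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], s + w))
        else:
            regions.append((s, s + w))
    return regions


def predict_g4(
    chrom_seq: str,
    chrom_name: str,
    params: G4HunterParams | None = None,
) -> list[G4Prediction]:
    """Predict G4 candidate regions on one chromosome sequence.

    Returns predictions sorted by start, with plus- and minus-strand
    regions reported independently (same-strand regions never overlap).
    A sequence shorter than the window yields an empty list with a
    warning.
    """
    params = params or G4HunterParams()
    w = params.window
    if len(chrom_seq) < w:
        warnings.warn(
            f"{chrom_name}: sequence shorter than window ({len(chrom_seq)} < {w}); "
            "no predictions made",
            stacklevel=2,
        )
        return []
    scores = base_scores(chrom_seq)
    plus_starts, minus_starts = _qualifying_window_starts(scores, w, params.threshold)
    preds: list[G4Prediction] = []
    for starts, strand in ((plus_starts, "+"), (minus_starts, "-")):
        for s, e in _merge_starts(starts, w):
            mean = float(scores[s:e].mean())
            preds.append(
                G4Prediction(
                    interval=GenomicInterval(chrom_name, s, e, strand, score=mean),
                    mean_score=mean,
                    sequence=chrom_seq[s:e].upper(),
                )
            )
    preds.sort(key=lambda p: (p.interval.start, p.interval.end, p.strand))
    return preds


def predict_genome(genome: Genome, params: G4HunterParams | None = None) -> list[G4Prediction]:
    """Run :func:`predict_g4` over every chromosome of a genome."""
    preds: list[G4Prediction] = []
    for chrom in genome.keys():
        preds.extend(predict_g4(genome.fetch(chrom, 0, genome.length(chrom)), chrom, params))
    return preds
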