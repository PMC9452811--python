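"""G4 feet: flanking-sequence extraction, 6-mer enrichment and motif
clustering.

A "foot" pair is the two <= 50-bp windows immediately flanking a
predicted G4, reported in the G4's sense orientation (minus-strand G4s
get reverse-complemented, role-swapped windows). K-mer frequencies are
per-site presence fractions: the fraction of G4 sites whose left OR
right foot contains the k-mer at least once. Enrichment of a target
foot set against a background set uses an upper-tail binomial test with
the background presence frequency as the null rate (floored at
``1/(2*N_background)`` to avoid degenerate nulls), Bonferroni-corrected
over all 4^k k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

from .hunter import G4Prediction, revcomp
from .intervals import Genome

__all__ = [
    "FootPair",
    "KmerEnrichment",
    "MotifCluster",
    "extract_feet",
    "kmer_presence",
    "enrichment_test",
    "filter_significant",
    "cluster_motifs",
    "write_feet_fasta",
    "write_meme_motifs",
]

BASES = "ACGT"


@dataclass(frozen=True)
class FootPair:
    """Flanking sequences of one G4, in G4 sense orientation."""

    g4_id: str
    left: str  # 5' of the G4 in its own orientation
    right: str  # 3'


@dataclass(frozen=True)
class KmerEnrichment:
    kmer: str
    freq_target: float
    freq_background: float
    n_target: int
    N_target: int
    fe: float  # fold enrichment, freq_target / floored background freq
    p: float
    p_adj: float


@dataclass
class MotifCluster:
    """A greedy k-mer cluster with a position-frequency matrix.

    ``members`` maps each k-mer to its alignment offset relative to the
    PFM's first column. Columns not covered by a member are padded with
    that member's weight spread uniformly over the four bases, so every
    PFM column sums to the cluster's total weight.
    """

    members: dict[str, int] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    pfm: np.ndarray | None = None  # shape (4, width), rows in BASES order
    consensus: str = ""


def extract_feet(
    predictions: list[G4Prediction], genome: Genome, flank: int = 50
) -> list[FootPair]:
    """Extract the two flanking windows of each prediction.

    For a '+' G4 [s, e): left = [s-flank, s), right = [e, e+flank); for
    a '-' G4 both windows are reverse-complemented and swapped so that
    'left' is 5' in G4 sense. Windows are clipped at chromosome bounds.
    Feet never include G4 bases.
    """
    feet = []
    for i, pred in enumerate(predictions):
        iv = pred.interval
        if iv.chrom not in genome.keys() or iv.end > genome.length(iv.chrom):
            raise ValueError(f"G4 {iv.chrom}:{iv.start}-{iv.end} outside genome")
        left_plus = genome.fetch(iv.chrom, iv.start - flank, iv.start)
        right_plus = genome.fetch(iv.chrom, iv.end, iv.end + flank)
        g4_id = iv.name or f"g4_{i}"
        if iv.strand == "-":
            feet.append(FootPair(g4_id, revcomp(right_plus), revcomp(left_plus)))
        else:
            feet.append(FootPair(g4_id, left_plus, right_plus))
    return feet


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(BASES, repeat=k)]


def kmer_presence(feet: list[FootPair], k: int = 6) -> dict[str, float]:
    """Per-site presence fraction for every k-mer.

    A k-mer's frequency is the fraction of G4 sites whose left or right
    foot contains it at least once (presence/absence per site, not
    occurrence counts).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for fp in feet:
        seen: set[str] = set()
        for seq in (fp.left, fp.right):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    seen.add(kmer)
        for kmer in seen:
            counts[kmer] = counts.get(kmer, 0) + 1
    n = max(len(feet), 1)
    return {m: counts.get(m, 0) / n for m in all_kmers(k)}


def enrichment_test(
    target_table: dict[str, float],
    background_table: dict[str, float],
    N_target: int,
    N_background: int,
) -> list[KmerEnrichment]:
    """Binomial enrichment of target presence over background, per k-mer.

    For each k-mer: the null rate is the background presence frequency
    floored at ``1/(2*N_background)``; p = P(X >= n_target) for X ~
    Binomial(N_target, rate); fold enrichment = freq_target / rate;
    Bonferroni correction over the full 4^k family.
    """
    if N_target <= 0:
        raise ValueError("N_target must be positive")
    if set(target_table) != set(background_table):
        raise ValueError("target and background tables cover different k-mer sets")
    floor = 1.0 / (2.0 * N_background) if N_background > 0 else 0.5
    family = len(target_table)
    out = []
    for kmer in sorted(target_table):
        ft = target_table[kmer]
        fb = background_table[kmer]
        rate = max(fb, floor)
        n_t = int(round(ft * N_target))
        p = float(stats.binom.sf(n_t - 1, N_target, rate))
        out.append(
            KmerEnrichment(
                kmer=kmer,
                freq_target=ft,
                freq_background=fb,
                n_target=n_t,
                N_target=N_target,
                fe=ft / rate,
                p=p,
                p_adj=min(1.0, p * family),
            )
        )
    return out


def filter_significant(
    results: list[KmerEnrichment],
    p_adj_max: float = 0.05,
    fe_min: float = 4.0,
    freq_min: float = 0.02,
) -> list[KmerEnrichment]:
    """Apply the published filters with strict inequalities:
    p_adj < 0.05, fold enrichment > 4, target frequency > 0.02."""
    return [
        r
        for r in results
        if r.p_adj < p_adj_max and r.fe > fe_min and r.freq_target > freq_min
    ]


def _align(kmer: str, consensus: str, max_shift: int = 2) -> tuple[int, int, int]:
    """Best ungapped alignment of kmer to consensus over shifts
    -max_shift..+max_shift. Returns (shift, n_overlap, n_mismatch) with
    the most matches (overlap - mismatches)."""
    best = (0, 0, len(kmer) + 1)
    best_score = -1
    for shift in range(-max_shift, max_shift + 1):
        overlap = mismatch = 0
        for i, base in enumerate(kmer):
            j = i + shift
            if 0 <= j < len(consensus):
                overlap += 1
                if consensus[j] != base:
                    mismatch += 1
        score = overlap - 2 * mismatch
        if overlap and score > best_score:
            best_score = score
            best = (shift, overlap, mismatch)
    return best


def _rebuild(cluster: MotifCluster) -> None:
    """Recompute PFM and consensus from members and weights."""
    lo = min(cluster.members.values())
    if lo != 0:  # renormalize offsets so the PFM starts at column 0
        cluster.members = {m: off - lo for m, off in cluster.members.items()}
    width = max(off + len(m) for m, off in cluster.members.items())
    pfm = np.zeros((4, width))
    total = sum(cluster.weights.values())
    for kmer, off in cluster.members.items():
        w = cluster.weights[kmer]
        covered = np.zeros(width, dtype=bool)
        for i, base in enumerate(kmer):
            pfm[BASES.index(base), off + i] += w
            covered[off + i] = True
        pfm[:, ~covered] += w / 4.0  # background padding keeps column sums equal
    cluster.pfm = pfm
    cluster.consensus = "".join(BASES[int(np.argmax(pfm[:, j]))] for j in range(width))
    assert np.allclose(pfm.sum(axis=0), total)


def cluster_motifs(
    kmer_freqs: dict[str, float],
    min_overlap: int = 4,
    max_mismatch: int = 1,
    max_shift: int = 2,
) -> list[MotifCluster]:
    """Greedy clustering of significant k-mers into PFMs.

    Seeds with the highest-frequency unassigned k-mer; a k-mer joins a
    cluster when its best ungapped alignment to the cluster consensus
    (shifts -max_shift..+max_shift) covers >= min_overlap positions with
    <= max_mismatch mismatches. The PFM is frequency-weighted; the
    consensus is recomputed after each join.
    """
    if not kmer_freqs:
        raise ValueError("no k-mers to cluster")
    unassigned = sorted(kmer_freqs, key=lambda m: (-kmer_freqs[m], m))
    clusters: list[MotifCluster] = []
    while unassigned:
        seed = unassigned.pop(0)
        cluster = MotifCluster(members={seed: 0}, weights={seed: kmer_freqs[seed]})
        _rebuild(cluster)
        changed = True
        while changed:
            changed = False
            for kmer in list(unassigned):
                shift, overlap, mismatch = _align(kmer, cluster.consensus, max_shift)
                if overlap >= min_overlap and mismatch <= max_mismatch:
                    cluster.members[kmer] = shift
                    cluster.weights[kmer] = kmer_freqs[kmer]
                    _rebuild(cluster)
                    unassigned.remove(kmer)
                    changed = True
        clusters.append(cluster)
    return clusters


def write_feet_fasta(feet: list[FootPair], path: str) -> None:
    with open(path, "w") as fh:
        for fp in feet:
            if fp.left:
                fh.write(f">{fp.g4_id}/left\n{fp.left}\n")
            if fp.right:
                fh.write(f">{fp.g4_id}/right\n{fp.right}\n")


def write_meme_motifs(clusters: list[MotifCluster], path: str) -> None:
    """Write cluster PFMs in MEME minimal motif format (probabilities)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for i, cl in enumerate(clusters, 1):
            probs = cl.pfm / cl.pfm.sum(axis=0, keepdims=True)
            width = probs.shape[1]
            fh.write(f"MOTIF cluster_{i} {cl.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {width} "
                f"nsites= {len(cl.members)} E= 0\n"
            )
            for j in range(width):
                fh.write(" ".join(f"{probs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")
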