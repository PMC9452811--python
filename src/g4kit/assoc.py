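"""Gene-level G4 association: labels, antisense flags, expression
comparisons and hypergeometric enrichment.

A gene's window (upstream 10 kb / transcript body / downstream 2 kb) is
labelled by an evidence hierarchy: G4-II if at least one G4-II overlaps
it, else G4-I, else G4-III, else noG4.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import GeneModel
from .evidence import EvidenceGroups
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GeneG4Label",
    "ExpressionRecord",
    "EnrichmentResult",
    "label_genes",
    "antisense_flag",
    "compare_expression",
    "hypergeom_enrichment",
    "read_expression",
]

REGIONS = ("upstream", "body", "downstream")
LABELS = ("G4-II", "G4-I", "G4-III", "noG4")


@dataclass(frozen=True)
class GeneG4Label:
    gene_id: str
    region: str
    label: str


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"{self.gene_id}: negative RPKM")


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric test of k marked in a sample of n,
    drawn from N items of which K are marked."""

    population: int
    marked: int
    sample: int
    observed: int
    p: float


def _gene_window(gene: GeneModel, region: str) -> GenomicInterval | None:
    if region == "upstream":
        return gene.upstream_window()
    if region == "body":
        return gene.body_window()
    if region == "downstream":
        return gene.downstream_window()
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def _any_overlap(window: GenomicInterval, by_chrom: dict[str, list[GenomicInterval]]) -> bool:
    for iv in by_chrom.get(window.chrom, []):
        if iv.start >= window.end:
            break
        if iv.end > window.start:
            return True
    return False


def label_genes(
    genes: list[GeneModel], groups: EvidenceGroups, region: str = "upstream"
) -> list[GeneG4Label]:
    """Label each gene's window by the evidence hierarchy II > I > III."""
    hier = [("G4-II", groups.g4_II.by_chrom()), ("G4-I", groups.g4_I.by_chrom()),
            ("G4-III", groups.g4_III.by_chrom())]
    out = []
    for gene in genes:
        window = _gene_window(gene, region)
        label = "noG4"
        if window is not None:
            for name, by_chrom in hier:
                if _any_overlap(window, by_chrom):
                    label = name
                    break
        out.append(GeneG4Label(gene.gene_id, region, label))
    return out


def antisense_flag(gene: GeneModel, g4_II: IntervalSet) -> bool:
    """True iff >= 1 G4-II lies within the gene body on the strand
    opposite the gene's strand (template strand)."""
    for iv in g4_II.intervals:
        if iv.strand == ".":
            raise ValueError("antisense logic requires stranded G4-II entries")
        if (
            iv.chrom == gene.chrom
            and iv.strand != gene.strand
            and iv.start >= gene.tx_start
            and iv.end <= gene.tx_end
        ):
            return True
    return False


def compare_expression(
    labels_a: list[GeneG4Label],
    labels_b: list[GeneG4Label],
    expr: dict[str, float],
) -> dict[str, float]:
    """Welch two-sample t-test on log2(RPKM+1) plus raw median fold.

    Returns ``{"t": ..., "p": ..., "median_fold": ...}`` where
    median_fold = median(A)/median(B) on the raw RPKM scale.
    """
    a = np.array([expr[l.gene_id] for l in labels_a if l.gene_id in expr])
    b = np.array([expr[l.gene_id] for l in labels_b if l.gene_id in expr])
    for side, vals in (("A", a), ("B", b)):
        if vals.size < 2:
            name = (labels_a if side == "A" else labels_b)
            lbl = name[0].label if name else "<empty>"
            raise ValueError(f"side {side} ({lbl}) has fewer than 2 genes with expression")
    t, p = stats.ttest_ind(np.log2(a + 1), np.log2(b + 1), equal_var=False)
    med_b = float(np.median(b))
    fold = float(np.median(a)) / med_b if med_b > 0 else float("inf")
    return {"t": float(t), "p": float(p), "median_fold": fold}


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts marked items in a sample of ``n`` drawn without replacement
    from ``N`` items of which ``K`` are marked.
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(population=N, marked=K, sample=n, observed=k, p=p)


def read_expression(path: str | os.PathLike) -> dict[str, float]:
    """Read a two-column expression TSV (gene_id, rpkm) with header."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    recs = [ExpressionRecord(r.gene_id, float(r.rpkm)) for r in df.itertuples(index=False)]
    return {r.gene_id: r.rpkm for r in recs}
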