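import numpy as np
import pytest

from g4kit import evidence, hunter, intervals, synthio
from g4kit.intervals import GenomicInterval, IntervalSet

# ---------------------------------------------------------------------------
# Brute-force per-base oracles (independent of the interval algebra)
# ---------------------------------------------------------------------------

def bases_covered(iset: IntervalSet, chrom_len: int = 2000) -> dict[str, np.ndarray]:
    """Boolean per-base coverage arrays, one per chromosome."""
    chroms = {iv.chrom for iv in iset.intervals}
    cover = {c: np.zeros(chrom_len, dtype=bool) for c in chroms}
    for iv in iset.intervals:
        cover[iv.chrom][iv.start : iv.end] = True
    return cover


def oracle_union_bp(iset: IntervalSet, chrom_len: int = 2000) -> int:
    return sum(int(a.sum()) for a in bases_covered(iset, chrom_len).values())


def oracle_intersect_bp(a: IntervalSet, b: IntervalSet, chrom_len: int = 2000) -> int:
    ca, cb = bases_covered(a, chrom_len), bases_covered(b, chrom_len)
    total = 0
    for chrom in set(ca) & set(cb):
        total += int((ca[chrom] & cb[chrom]).sum())
    return total


def random_interval_set(rng, n=20, chrom="toy", chrom_len=1000, name="r") -> IntervalSet:
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, chrom_len - 2))
        e = int(rng.integers(s + 1, min(chrom_len, s + 60) + 1))
        ivs.append(GenomicInterval(chrom, s, e))
    return IntervalSet(name, ivs)


# ---------------------------------------------------------------------------
# Shared synthetic bundle (small, fast) and derived pipeline objects
# ---------------------------------------------------------------------------

SMALL_CONFIG = dict(
    n_chroms=2,
    chrom_length=340_000,
    n_free_g4_per_strand=8,
    n_genes=20,
    n_background_cpg=300,
    seed=7,
)


@pytest.fixture(scope="session")
def bundle():
    return synthio.simulate(synthio.SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def genome(bundle):
    return intervals.Genome(bundle.genome)


@pytest.fixture(scope="session")
def predictions(bundle, genome):
    return hunter.predict_genome(genome)


@pytest.fixture(scope="session")
def groups(bundle, predictions):
    return evidence.classify(predictions, bundle.peaks)
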