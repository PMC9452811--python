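"""Seeded synthetic-data generator for every pipeline input.

Produces a genome with planted G4 consensus motifs (four G-runs split by
short loops) on both strands, ChIP-style peaks capturing a tunable
fraction of plantings, gene models whose upstream/body G4 context is
drawn from configurable intention probabilities, epigenomic tracks
co-localizing with upstream windows, TF peak sets, a CpG methylation
table drawn from a hypo/intermediate/hyper mixture (hypo up-weighted in
high-confidence G4 context), and expression sampled from a logistic
model (the published equation by default). All randomness flows from a
single seed; outputs are byte-identical across runs.

Layout: each chromosome starts with a gene-free zone (free plantings,
false peaks, random track intervals), followed by disjoint gene slots
sized so 10-kb upstream and 2-kb downstream windows never overlap a
neighbouring slot. Background sequence is A/T-rich so spurious
predictions are vanishingly rare and planted-recovery tests are sharp.
Plantings are padded with short A/T buffers and use G-runs of length 4+
so every planting scores above the default prediction threshold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .annotate import GeneModel, write_gene_table
from .evidence import EvidenceGroups
from .hunter import G4Prediction, revcomp
from .intervals import GenomicInterval, IntervalSet, write_bed
from .model import FEATURE_NAMES, PRINTED_MODEL, FeatureVector, FittedModel, predict_logodds
from .tracks import MethylRecord

__all__ = ["SimConfig", "TruthSet", "SimBundle", "simulate", "truth_report",
           "sample_feature_cohort", "write_bundle"]

# order matches the track block of model.FEATURE_NAMES
TRACK_NAMES = ("enhancer", "se", "cgi", "open_chrom")


@dataclass
class SimConfig:
    """Knobs for the simulator; every rate lies in [0, 1]."""

    n_chroms: int = 2
    chrom_length: int = 340_000
    # planted G4s outside gene slots, per strand and chromosome
    n_free_g4_per_strand: int = 10
    g4_run_len: tuple[int, int] = (4, 5)  # inclusive range of G-run lengths
    g4_loop_len: tuple[int, int] = (1, 3)  # inclusive range of loop lengths
    capture_rate: float = 0.6  # fraction of free plantings covered by a peak
    false_peak_rate: float = 0.2  # false peaks per free planting
    peak_slop: int = 30
    n_genes: int = 24
    gene_body_len: int = 4_000
    # categorical intention for each gene's upstream context
    upstream_probs: tuple[float, float, float, float] = (0.1, 0.2, 0.4, 0.3)
    # order: noG4, G4-I (peak only), G4-II (planting + peak), G4-III (planting only)
    antisense_prob: float = 0.3
    track_probs: dict = field(
        default_factory=lambda: {"cgi": 0.4, "enhancer": 0.3, "se": 0.15, "open_chrom": 0.5}
    )
    n_random_track: int = 4  # free-zone intervals per track
    track_len: int = 1_000
    tf_capture: dict = field(default_factory=lambda: {"TFA": 0.5, "TFB": 0.2, "TFC": 0.0})
    n_random_tf: int = 5
    cpg_per_g4: int = 5
    n_background_cpg: int = 500
    # beta-mixture weights (hypo, intermediate, hyper) per context
    beta_weights: dict = field(
        default_factory=lambda: {
            "G4-I": (0.50, 0.30, 0.20),
            "G4-II": (0.80, 0.15, 0.05),
            "G4-III": (0.55, 0.30, 0.15),
            "background": (0.60, 0.28, 0.12),
        }
    )
    mean_coverage: int = 30
    low_coverage_frac: float = 0.1
    expression_model: FittedModel = field(default_factory=lambda: PRINTED_MODEL)
    mu_high: float = 2.5
    mu_low: float = 0.0
    sigma: float = 1.0
    at_frac: float = 0.6  # background AT content
    seed: int = 0

    FREE_ZONE: int = 30_000
    GENE_MARGIN: int = 10_500  # reserved on both sides of a gene body

    def __post_init__(self) -> None:
        rates = [self.capture_rate, self.false_peak_rate, self.antisense_prob,
                 *self.upstream_probs, *self.track_probs.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if abs(sum(self.upstream_probs) - 1.0) > 1e-9:
            raise ValueError("upstream_probs must sum to 1")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("chromosome dimensions must be positive")


@dataclass
class TruthSet:
    """Ground truth recorded while simulating."""

    plantings: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    # (planted motif interval with strand, intended group "G4-II"/"G4-III")
    peak_only: list[GenomicInterval] = field(default_factory=list)  # intended G4-I peaks
    gene_features: dict[str, tuple[int, ...]] = field(default_factory=dict)
    gene_high: dict[str, int] = field(default_factory=dict)

    def planted_set(self) -> IntervalSet:
        return IntervalSet("planted", [iv for iv, _ in self.plantings])


@dataclass
class SimBundle:
    genome: dict[str, str]
    peaks: IntervalSet
    genes: list[GeneModel]
    tracks: dict[str, IntervalSet]
    tf_sets: dict[str, IntervalSet]
    methyl: list[MethylRecord]
    expression: dict[str, float]
    truth: TruthSet
    config: SimConfig


def _g4_motif(rng: np.random.Generator, cfg: SimConfig, strand: str) -> str:
    """One canonical consensus instance: four G-runs with A/T loops."""
    runs = rng.integers(cfg.g4_run_len[0], cfg.g4_run_len[1] + 1, size=4)
    loops = rng.integers(cfg.g4_loop_len[0], cfg.g4_loop_len[1] + 1, size=3)
    parts = []
    for i, r in enumerate(runs):
        parts.append("G" * int(r))
        if i < 3:
            parts.append("".join(rng.choice(["A", "T"], size=int(loops[i]))))
    motif = "".join(parts)
    return motif if strand == "+" else revcomp(motif)


def _background(rng: np.random.Generator, n: int, at_frac: float) -> np.ndarray:
    """A/T-rich background with G/C runs capped at 2.

    The run cap keeps every 25-bp window far below the default
    prediction threshold, so all predictions trace back to plantings.
    """
    p_at = at_frac / 2.0
    p_gc = (1.0 - at_frac) / 2.0
    seq = rng.choice(np.array(list("ATGC")), size=n, p=[p_at, p_at, p_gc, p_gc])
    ats = rng.choice(np.array(list("AT")), size=n)
    if n >= 3:
        # every position that is the 3rd+ base of a G/C run gets an A/T;
        # one pass suffices (runs shrink to 2, replacements are A/T)
        run3 = (
            (seq[2:] == seq[1:-1])
            & (seq[1:-1] == seq[:-2])
            & np.isin(seq[2:], list("GC"))
        )
        idx = np.flatnonzero(run3) + 2
        seq[idx] = ats[idx]
    return seq


def _plant(seq: np.ndarray, pos: int, motif: str, buffer: int = 10) -> None:
    """Write motif at pos with A/T buffers so flanks never perturb scores."""
    seq[max(0, pos - buffer): pos] = "A"
    seq[pos: pos + len(motif)] = list(motif)
    end = pos + len(motif)
    seq[end: end + buffer] = "T"


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate the full synthetic input bundle with ground truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.gene_body_len + 2 * cfg.GENE_MARGIN
    slots_per_chrom = (cfg.chrom_length - cfg.FREE_ZONE) // slot
    if slots_per_chrom * cfg.n_chroms < cfg.n_genes:
        raise ValueError(
            f"chromosomes too short: room for {slots_per_chrom * cfg.n_chroms} "
            f"genes, requested {cfg.n_genes}"
        )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {c: _background(rng, cfg.chrom_length, cfg.at_frac) for c in chrom_names}
    truth = TruthSet()
    peaks: list[GenomicInterval] = []

    def add_peak(chrom: str, start: int, end: int) -> None:
        peaks.append(GenomicInterval(chrom, max(0, start), min(cfg.chrom_length, end)))

    # --- free-zone plantings -------------------------------------------------
    for chrom in chrom_names:
        positions: list[int] = []
        lo, hi = 100, cfg.FREE_ZONE - 200
        for strand in ("+", "-"):
            for _ in range(cfg.n_free_g4_per_strand):
                motif = _g4_motif(rng, cfg, strand)
                for _ in range(200):  # rejection sampling, min 80-bp spacing
                    pos = int(rng.integers(lo, hi))
                    if all(abs(pos - p) >= 80 for p in positions):
                        break
                else:
                    raise ValueError("free zone too crowded for requested plantings")
                positions.append(pos)
                _plant(seqs[chrom], pos, motif)
                iv = GenomicInterval(chrom, pos, pos + len(motif), strand)
                captured = rng.random() < cfg.capture_rate
                truth.plantings.append((iv, "G4-II" if captured else "G4-III"))
                if captured:
                    slop = int(rng.integers(5, cfg.peak_slop))
                    add_peak(chrom, pos - slop, pos + len(motif) + slop)
        # false peaks: in the free zone, away from every planting
        n_false = int(round(cfg.false_peak_rate * 2 * cfg.n_free_g4_per_strand))
        for _ in range(n_false):
            for _ in range(200):
                pos = int(rng.integers(lo, hi))
                if all(abs(pos - p) >= 350 for p in positions):
                    break
            else:
                continue
            positions.append(pos)
            width = int(rng.integers(60, 200))
            add_peak(chrom, pos, pos + width)
            truth.peak_only.append(GenomicInterval(chrom, pos, pos + width))

    # --- genes and their intended G4/track context ---------------------------
    genes: list[GeneModel] = []
    tracks: dict[str, list[GenomicInterval]] = {t: [] for t in TRACK_NAMES}
    g4_ii_plantings: list[GenomicInterval] = []
    gene_idx = 0
    for chrom in chrom_names:
        for s in range(slots_per_chrom):
            if gene_idx >= cfg.n_genes:
                break
            slot_start = cfg.FREE_ZONE + s * slot
            strand = "+" if rng.random() < 0.5 else "-"
            tx_start = slot_start + cfg.GENE_MARGIN
            tx_end = tx_start + cfg.gene_body_len
            body = cfg.gene_body_len
            exons = (
                (tx_start, tx_start + body // 5),
                (tx_start + 2 * body // 5, tx_start + 3 * body // 5),
                (tx_end - body // 5, tx_end),
            )
            cds_start = tx_start + body // 10
            cds_end = tx_end - body // 10
            gene = GeneModel(
                gene_id=f"gene{gene_idx:04d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
            )
            genes.append(gene)
            up = gene.upstream_window()
            intent = int(rng.choice(4, p=cfg.upstream_probs))
            onehot = [0, 0, 0]
            if intent in (2, 3):  # plant a G4 in the upstream window
                motif = _g4_motif(rng, cfg, strand)
                pos = int(rng.integers(up.start + 100, up.end - len(motif) - 100))
                _plant(seqs[chrom], pos, motif)
                iv = GenomicInterval(chrom, pos, pos + len(motif), strand)
                group = "G4-II" if intent == 2 else "G4-III"
                truth.plantings.append((iv, group))
                if intent == 2:
                    add_peak(chrom, pos - 20, pos + len(motif) + 20)
                    g4_ii_plantings.append(iv)
                    onehot[1] = 1
                else:
                    onehot[2] = 1
            elif intent == 1:  # peak only, no planting anywhere near
                pos = int(rng.integers(up.start + 100, up.end - 400))
                width = int(rng.integers(80, 250))
                add_peak(chrom, pos, pos + width)
                truth.peak_only.append(GenomicInterval(chrom, pos, pos + width))
                onehot[0] = 1

            track_bits = []
            for tname in TRACK_NAMES:
                bit = int(rng.random() < cfg.track_probs[tname])
                if bit:
                    t0 = int(rng.integers(up.start, up.end - cfg.track_len))
                    tracks[tname].append(GenomicInterval(chrom, t0, t0 + cfg.track_len))
                track_bits.append(bit)

            anti = 0
            if rng.random() < cfg.antisense_prob:
                anti_strand = "-" if strand == "+" else "+"
                motif = _g4_motif(rng, cfg, anti_strand)
                pos = int(rng.integers(tx_start + 60, tx_end - len(motif) - 60))
                _plant(seqs[chrom], pos, motif)
                iv = GenomicInterval(chrom, pos, pos + len(motif), anti_strand)
                truth.plantings.append((iv, "G4-II"))
                add_peak(chrom, pos - 20, pos + len(motif) + 20)
                g4_ii_plantings.append(iv)
                anti = 1

            truth.gene_features[gene.gene_id] = tuple(onehot + track_bits + [anti])
            gene_idx += 1

    # random track intervals confined to the free zone
    for tname in TRACK_NAMES:
        for _ in range(cfg.n_random_track):
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            t0 = int(rng.integers(0, cfg.FREE_ZONE - cfg.track_len))
            tracks[tname].append(GenomicInterval(chrom, t0, t0 + cfg.track_len))

    # --- TF peak sets --------------------------------------------------------
    all_ii = [iv for iv, g in truth.plantings if g == "G4-II"]
    tf_sets: dict[str, IntervalSet] = {}
    for tf, rate in cfg.tf_capture.items():
        ivs = []
        for iv in all_ii:
            if rng.random() < rate:
                ivs.append(GenomicInterval(iv.chrom, max(0, iv.start - 15), iv.end + 15))
        for _ in range(cfg.n_random_tf):
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            t0 = int(rng.integers(0, cfg.FREE_ZONE - 300))
            ivs.append(GenomicInterval(chrom, t0, t0 + int(rng.integers(100, 300))))
        tf_sets[tf] = IntervalSet(tf, ivs)

    # --- methylation ---------------------------------------------------------
    def draw_beta(context: str) -> float:
        w = cfg.beta_weights[context]
        comp = rng.choice(3, p=np.asarray(w) / sum(w))
        if comp == 0:
            return float(rng.uniform(0.0, 0.1))
        if comp == 1:
            return float(rng.uniform(0.11, 0.89))
        return float(rng.uniform(0.9, 1.0))

    def draw_coverage() -> int:
        if rng.random() < cfg.low_coverage_frac:
            return int(rng.integers(0, 10))
        return int(rng.poisson(cfg.mean_coverage))

    methyl: list[MethylRecord] = []
    for iv, group in truth.plantings:
        for _ in range(cfg.cpg_per_g4):
            pos = int(rng.integers(iv.start, iv.end))
            methyl.append(MethylRecord(iv.chrom, pos, draw_coverage(), draw_beta(group)))
    for iv in truth.peak_only:
        for _ in range(cfg.cpg_per_g4):
            pos = int(rng.integers(iv.start, iv.end))
            methyl.append(MethylRecord(iv.chrom, pos, draw_coverage(), draw_beta("G4-I")))
    for _ in range(cfg.n_background_cpg):
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(0, cfg.chrom_length))
        methyl.append(MethylRecord(chrom, pos, draw_coverage(), draw_beta("background")))
    methyl.sort(key=lambda r: (r.chrom, r.pos))

    # --- expression from the configured logistic model -----------------------
    expression: dict[str, float] = {}
    for gene in genes:
        fv = truth.gene_features[gene.gene_id]
        y = predict_logodds(cfg.expression_model, fv)
        p_high = 1.0 / (1.0 + np.exp(-y))
        high = int(rng.random() < p_high)
        truth.gene_high[gene.gene_id] = high
        mu = cfg.mu_high if high else cfg.mu_low
        expression[gene.gene_id] = float(np.exp(rng.normal(mu, cfg.sigma)))

    return SimBundle(
        genome={c: "".join(seqs[c]) for c in chrom_names},
        peaks=IntervalSet("peaks", peaks),
        genes=genes,
        tracks={t: IntervalSet(t, ivs) for t, ivs in tracks.items()},
        tf_sets=tf_sets,
        methyl=methyl,
        expression=expression,
        truth=truth,
        config=cfg,
    )


def sample_feature_cohort(
    n: int,
    model: FittedModel = PRINTED_MODEL,
    seed: int = 0,
    upstream_probs: tuple[float, float, float, float] = (0.1, 0.25, 0.4, 0.25),
    track_probs: tuple[float, ...] = (0.3, 0.15, 0.4, 0.5),
    antisense_prob: float = 0.3,
) -> tuple[list[FeatureVector], dict[str, int]]:
    """Sample (features, labels) directly from the logistic model.

    Upstream indicators are drawn as a categorical one-hot
    (noG4/I/II/III), track and antisense bits as independent Bernoullis;
    labels are Bernoulli(sigmoid(log-odds)). Used for parameter-recovery
    and null simulations.
    """
    rng = np.random.default_rng(seed)
    features: list[FeatureVector] = []
    labels: dict[str, int] = {}
    for i in range(n):
        intent = int(rng.choice(4, p=upstream_probs))
        onehot = [int(intent == 1), int(intent == 2), int(intent == 3)]
        bits = [int(rng.random() < p) for p in track_probs]
        anti = int(rng.random() < antisense_prob)
        fv = FeatureVector(f"g{i:05d}", tuple(onehot + bits + [anti]))
        y = predict_logodds(model, fv)
        labels[fv.gene_id] = int(rng.random() < 1.0 / (1.0 + np.exp(-y)))
        features.append(fv)
    return features, labels


def truth_report(
    truth: TruthSet,
    predictions: list[G4Prediction],
    groups: EvidenceGroups | None = None,
    computed_features: dict[str, tuple[int, ...]] | None = None,
) -> dict:
    """Recovery metrics of pipeline outputs against simulator truth.

    sensitivity: fraction of plantings overlapped by a same-strand
    prediction; precision: fraction of predictions overlapping a
    planting; group confusion: intended vs assigned evidence tier;
    feature agreement: fraction of genes with exactly the intended
    feature vector.
    """
    report: dict = {}
    if not truth.plantings:
        report["sensitivity"] = None
        report["precision"] = None
    else:
        pred_ivs = [p.interval for p in predictions]
        recovered = sum(
            1
            for iv, _ in truth.plantings
            if any(iv.overlaps(p) and iv.strand == p.strand for p in pred_ivs)
        )
        report["sensitivity"] = recovered / len(truth.plantings)
        if pred_ivs:
            matched = sum(
                1
                for p in pred_ivs
                if any(p.overlaps(iv) and p.strand == iv.strand for iv, _ in truth.plantings)
            )
            report["precision"] = matched / len(pred_ivs)
        else:
            report["precision"] = None

    if groups is not None:
        confusion: dict[str, dict[str, int]] = {}
        assigned_sets = groups.as_dict()
        for iv, intended in truth.plantings:
            assigned = "missed"
            for gname in ("G4-II", "G4-III"):
                if any(iv.overlaps(a) for a in assigned_sets[gname].intervals):
                    assigned = gname
                    break
            confusion.setdefault(intended, {}).setdefault(assigned, 0)
            confusion[intended][assigned] += 1
        for iv in truth.peak_only:
            assigned = (
                "G4-I"
                if any(iv.overlaps(a) for a in assigned_sets["G4-I"].intervals)
                else "missed"
            )
            confusion.setdefault("G4-I", {}).setdefault(assigned, 0)
            confusion["G4-I"][assigned] += 1
        report["group_confusion"] = confusion

    if computed_features is not None and truth.gene_features:
        agree = sum(
            1
            for gid, fv in truth.gene_features.items()
            if computed_features.get(gid) == fv
        )
        report["feature_agreement"] = agree / len(truth.gene_features)
    return report


# ---------------------------------------------------------------------------
# Bundle writing (plain-text standard formats)
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(bundle: SimBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every input file of the bundle; returns a name->path map."""
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {}

    paths["fasta"] = os.path.join(out, "genome.fa")
    write_fasta(bundle.genome, paths["fasta"])
    paths["peaks"] = os.path.join(out, "peaks.bed")
    write_bed(bundle.peaks, paths["peaks"])
    paths["genes"] = os.path.join(out, "genes.tsv")
    write_gene_table(bundle.genes, paths["genes"])
    for tname, iset in bundle.tracks.items():
        paths[f"track_{tname}"] = os.path.join(out, f"track_{tname}.bed")
        write_bed(iset, paths[f"track_{tname}"])
    for tf, iset in bundle.tf_sets.items():
        paths[f"tf_{tf}"] = os.path.join(out, f"tf_{tf}.bed")
        write_bed(iset, paths[f"tf_{tf}"])
    paths["methyl"] = os.path.join(out, "methylation.tsv")
    with open(paths["methyl"], "w") as fh:
        for r in bundle.methyl:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 2}\t{r.coverage}\t{r.beta:.6f}\n")
    paths["expression"] = os.path.join(out, "expression.tsv")
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\trpkm\n")
        for gid in sorted(bundle.expression):
            fh.write(f"{gid}\t{bundle.expression[gid]:.6f}\n")
    paths["truth"] = os.path.join(out, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "plantings": [
                    {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "strand": iv.strand, "group": g}
                    for iv, g in bundle.truth.plantings
                ],
                "peak_only": [
                    {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                    for iv in bundle.truth.peak_only
                ],
                "gene_features": {
                    gid: list(fv) for gid, fv in bundle.truth.gene_features.items()
                },
                "gene_high": bundle.truth.gene_high,
                "feature_names": list(FEATURE_NAMES),
            },
            fh,
            indent=1,
        )
    return paths
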