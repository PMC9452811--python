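"""Eight-feature penalized logistic model of high/low gene expression.

Features are binary indicators per gene, in fixed order:

0. g4I_up      — upstream label is G4-I
1. g4II_up     — upstream label is G4-II
2. g4III_up    — upstream label is G4-III
3. enhancer    — 10-kb upstream window overlaps the enhancer track
4. se          — ... the super-enhancer track
5. cgi         — ... the CpG-island track
6. open_chrom  — ... the open-chromatin track
7. antisense   — >= 1 G4-II on the gene-body template strand

The three upstream indicators are a mutually exclusive one-hot of the
evidence-hierarchy label (noG4 genes get all three zero). The packaged
``PRINTED_MODEL`` carries the published equation's intercept and
coefficients so it can be applied without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .annotate import GeneModel
from .assoc import antisense_flag, label_genes
from .evidence import EvidenceGroups
from .intervals import IntervalSet

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FittedModel",
    "PRINTED_MODEL",
    "build_features",
    "make_labels",
    "split",
    "fit",
    "evaluate",
    "predict_logodds",
]

FEATURE_NAMES = (
    "g4I_up",
    "g4II_up",
    "g4III_up",
    "enhancer",
    "se",
    "cgi",
    "open_chrom",
    "antisense",
)

TRACK_FEATURES = ("enhancer", "se", "cgi", "open_chrom")


@dataclass(frozen=True)
class FeatureVector:
    gene_id: str
    values: tuple[int, ...]  # aligned to FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError("feature vector must have 8 entries")
        if any(v not in (0, 1) for v in self.values):
            raise ValueError("features must be binary")
        if sum(self.values[:3]) > 1:
            raise ValueError("upstream indicators must be mutually exclusive")


@dataclass
class FittedModel:
    """Intercept + eight coefficients, with training metadata."""

    intercept: float
    coefficients: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(FEATURE_NAMES):
            raise ValueError("model must carry 8 coefficients")


#: The published final equation (log-odds of high expression).
PRINTED_MODEL = FittedModel(
    intercept=-4.94,
    coefficients=(0.80, 1.60, -1.21, 0.56, 1.33, 1.73, 3.00, -0.15),
    meta={"source": "published final model"},
)


def build_features(
    genes: list[GeneModel],
    groups: EvidenceGroups,
    track_sets: dict[str, IntervalSet],
    g4_II: IntervalSet | None = None,
) -> list[FeatureVector]:
    """Per-gene binary feature vectors.

    ``track_sets`` maps the four track feature names to interval sets;
    a missing track yields zeros for that indicator. Track indicators
    are computed on the 10-kb upstream window.
    """
    g4_II = g4_II if g4_II is not None else groups.g4_II
    upstream_labels = {l.gene_id: l.label for l in label_genes(genes, groups, "upstream")}
    track_chrom = {
        name: track_sets[name].by_chrom() if name in track_sets else {}
        for name in TRACK_FEATURES
    }
    out = []
    for gene in genes:
        lab = upstream_labels[gene.gene_id]
        onehot = [int(lab == "G4-I"), int(lab == "G4-II"), int(lab == "G4-III")]
        window = gene.upstream_window()
        track_bits = []
        for name in TRACK_FEATURES:
            bit = 0
            if window is not None:
                for iv in track_chrom[name].get(window.chrom, []):
                    if iv.start >= window.end:
                        break
                    if iv.end > window.start:
                        bit = 1
                        break
            track_bits.append(bit)
        anti = int(antisense_flag(gene, g4_II))
        out.append(FeatureVector(gene.gene_id, tuple(onehot + track_bits + [anti])))
    return out


def make_labels(expr: dict[str, float], quantile: float = 0.25) -> dict[str, int]:
    """Quantile-extreme labels: top-quantile genes 1, bottom 0.

    The middle is excluded; ties at either cut are broken by gene_id
    lexicographic order so the labelling is deterministic and depends
    only on expression ranks.
    """
    if len(expr) < 8:
        raise ValueError("need >= 8 genes to form quantile classes")
    vals = list(expr.values())
    if min(vals) == max(vals):
        raise ValueError("expression is constant; no quantile separation")
    n_sel = int(len(expr) * quantile)
    if n_sel < 1 or 2 * n_sel > len(expr):
        raise ValueError(f"quantile {quantile} yields degenerate classes")
    by_low = sorted(expr, key=lambda g: (expr[g], g))
    by_high = sorted(expr, key=lambda g: (-expr[g], g))
    labels = {g: 0 for g in by_low[:n_sel]}
    for g in by_high[:n_sel]:
        labels[g] = 1
    return labels


def split(
    features: list[FeatureVector],
    labels: dict[str, int],
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified train/test split preserving the 1:1 class balance.

    Returns (train, test) lists of (FeatureVector, label) pairs; the
    same number of genes per class goes to each partition, and the
    split is deterministic under a fixed seed.
    """
    labelled = [(fv, labels[fv.gene_id]) for fv in features if fv.gene_id in labels]
    per_class = {0: [p for p in labelled if p[1] == 0], 1: [p for p in labelled if p[1] == 1]}
    if not per_class[0] or not per_class[1]:
        raise ValueError("both classes must be present to stratify")
    n_take = min(len(per_class[0]), len(per_class[1]))
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cls in (0, 1):
        pool = sorted(per_class[cls], key=lambda p: p[0].gene_id)
        order = rng.permutation(len(pool))[:n_take]
        n_train = int(round(n_take * train_frac))
        if n_train == 0 or n_train == n_take:
            raise ValueError("class too small to stratify at this train fraction")
        chosen = [pool[i] for i in order]
        train.extend(chosen[:n_train])
        test.extend(chosen[n_train:])
    return train, test


def _design(pairs: list) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p[0].values for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=int)
    return X, y


def fit(
    train: list,
    mixing: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    n_penalties: int = 20,
) -> FittedModel:
    """Elastic-net logistic regression; penalty strength chosen by CV.

    ``mixing`` is the L1 fraction of the penalty (0 = ridge, 1 = lasso).
    Constant features are retained (the penalty handles them) with a
    warning. Bitwise reproducible under a fixed seed.
    """
    X, y = _design(train)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(f"need >= {cv_folds} samples per class for {cv_folds}-fold CV")
    constant = [FEATURE_NAMES[j] for j in range(X.shape[1]) if len(np.unique(X[:, j])) == 1]
    if constant:
        import warnings

        warnings.warn(f"constant features retained: {constant}", stacklevel=2)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=n_penalties,
        cv=cv,
        solver="saga",
        l1_ratios=[mixing],
        scoring="neg_log_loss",
        max_iter=10_000,
        random_state=seed,
        use_legacy_attributes=False,
    )
    clf.fit(X, y)
    return FittedModel(
        intercept=float(np.atleast_1d(clf.intercept_)[0]),
        coefficients=tuple(float(c) for c in clf.coef_[0]),
        meta={
            "l1_ratio": mixing,
            "C": float(np.atleast_1d(clf.C_)[0]),
            "cv_folds": cv_folds,
            "seed": seed,
            "n_train": len(train),
        },
    )


def predict_logodds(model: FittedModel, fv: FeatureVector | tuple | list) -> float:
    """Linear predictor y = intercept + sum(coef_i * delta_i)."""
    values = fv.values if isinstance(fv, FeatureVector) else tuple(fv)
    return float(model.intercept + np.dot(model.coefficients, np.asarray(values, dtype=float)))


def evaluate(model: FittedModel, test: list) -> dict:
    """Accuracy, 2x2 confusion matrix and rank-based AUC on a test set.

    Classes are predicted at probability 0.5 (log-odds 0). A test set
    with one class present has no defined AUC and raises.
    """
    if not test:
        raise ValueError("test set is empty")
    X, y = _design(test)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test set has a single class")
    scores = model.intercept + X @ np.asarray(model.coefficients)
    pred = (scores > 0).astype(int)
    acc = float((pred == y).mean())
    cm = confusion_matrix(y, pred, labels=[0, 1])
    auc = float(roc_auc_score(y, scores))
    return {"accuracy": acc, "confusion": cm, "auc": auc}


def coefficients_frame(model: FittedModel) -> pd.DataFrame:
    rows = [{"feature": "(intercept)", "coefficient": model.intercept}]
    rows += [
        {"feature": n, "coefficient": c}
        for n, c in zip(FEATURE_NAMES, model.coefficients)
    ]
    return pd.DataFrame(rows)
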