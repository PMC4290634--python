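"""RBF-SVM models over sequence-window features.

Two model modes are supported:

* ``single`` — one SVM trained on all positive windows against a
  balanced negative sample;
* ``mdd_clustered`` — the positive windows are first partitioned into
  motif subgroups by maximal dependence decomposition; each leaf trains
  its own SVM on its members against negatives routed down the same
  tree, and a query window is scored by the model of the leaf it routes
  to.  An optional second-layer (stacking) SVM over all leaf
  probabilities is available but off by default.

Evaluation uses the confusion-count metrics sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/(TP+FP+TN+FN) and the Matthews correlation coefficient,
with five-fold cross-validation pooling the per-fold confusion counts
before computing metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from glycmotif.encoders import EncoderArtifacts, encode_fragments
from glycmotif.mdd import MDDConfig, MDDNode, mdd_cluster, route_fragment
from glycmotif.seqdata import (
    ProteinRecord,
    SequenceFragment,
    SiteRecord,
    WindowConfig,
    extract_fragment,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class SVMParams:
    """RBF kernel parameters: K(S_i, S_j) = exp(-gamma * ||S_i - S_j||^2)."""

    C: float = 1.0
    gamma: float = 0.0625

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


#: Default exhaustive grid: C in 2^-5..2^15, gamma in 2^-15..2^3, log2 steps of 2.
DEFAULT_GRID: list[SVMParams] = [
    SVMParams(C=2.0**c, gamma=2.0**g)
    for c in range(-5, 16, 2)
    for g in range(-15, 4, 2)
]

#: Reduced grid used by the desk-scale benchmark harness.
SMALL_GRID: list[SVMParams] = [
    SVMParams(C=2.0**c, gamma=2.0**g) for c in (0, 3) for g in (-7, -4)
]


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts plus the four derived metrics.

    Metrics with a zero denominator are reported as NaN (never silently
    as 0).  ``format_row`` renders the 2-decimal presentation used in
    results tables; raw values stay untouched.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def balanced_accuracy(self) -> float:
        return (self.sn + self.sp) / 2

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
        }

    def format_row(self) -> str:
        def fmt(x: float) -> str:
            return "nan" if math.isnan(x) else f"{x:.2f}"

        return " ".join(fmt(v) for v in (self.sn, self.sp, self.acc, self.mcc))


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalMetrics:
    """Sn/Sp/Acc/MCC from confusion counts (NaN where undefined)."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: float, den: float) -> float:
        if den == 0:
            logger.warning("metric undefined (zero denominator)")
            return math.nan
        return num / den

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = (tp + tn) / total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC undefined (zero denominator)")
        mcc = math.nan
    else:
        mcc = (tp * tn - fn * fp) / math.sqrt(denom)
    return EvalMetrics(tp, tn, fp, fn, sn, sp, acc, mcc)


def _fit_svc(X: np.ndarray, y: np.ndarray, params: SVMParams, seed: int) -> SVC:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    import warnings

    with warnings.catch_warnings():
        # scikit-learn 1.9 deprecates SVC(probability=True); the Platt
        # probability output is part of the model contract here.
        warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(
            kernel="rbf",
            C=params.C,
            gamma=params.gamma,
            probability=True,
            random_state=seed,
        )
        clf.fit(X, y)
    return clf


def _proba_positive(clf: SVC, X: np.ndarray) -> np.ndarray:
    col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(X)[:, col]


def grid_search(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    grid: Sequence[SVMParams] | None = None,
    k: int = 3,
    seed: int = 0,
) -> SVMParams:
    """Exhaustive (C, gamma) search maximizing CV balanced accuracy.

    The objective is (Sn + Sp)/2 pooled over an internal stratified
    k-fold split; ties go to the smaller C, then the smaller gamma.
    """
    grid = list(grid) if grid is not None else DEFAULT_GRID
    if not grid:
        raise ValueError("empty parameter grid")
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos), dtype=int), np.zeros(len(X_neg), dtype=int)])
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (-score, C, gamma)
    best_params = grid[0]
    for params in sorted(grid, key=lambda p: (p.C, p.gamma)):
        tp = fp = tn = fn = 0
        for train_idx, test_idx in folds:
            clf = _fit_svc(X[train_idx], y[train_idx], params, seed)
            pred = (_proba_positive(clf, X[test_idx]) >= 0.5).astype(int)
            truth = y[test_idx]
            tp += int(np.sum((pred == 1) & (truth == 1)))
            fp += int(np.sum((pred == 1) & (truth == 0)))
            tn += int(np.sum((pred == 0) & (truth == 0)))
            fn += int(np.sum((pred == 0) & (truth == 1)))
        score = (tp / (tp + fn) + tn / (tn + fp)) / 2
        key = (-score, params.C, params.gamma)
        if best is None or key < best:
            best = key
            best_params = params
    return best_params


@dataclass
class ModelBundle:
    """A trained model with everything needed to score new sites.

    ``models`` maps MDD leaf id to its fitted SVM (a single entry with
    key 0 in ``single`` mode); ``leaf_params`` records the (C, gamma)
    used per leaf.  ``artifacts`` carries training-derived encoders
    (PWM, PSSM profiles, ASA normalizer).  ``training_keys`` are the
    (protein_id, position) pairs seen in training, used to flag overlap
    with an independent test set.
    """

    mode: str  # "single" | "mdd_clustered"
    scheme: str
    models: dict[int, SVC]
    leaf_params: dict[int, SVMParams]
    tree: MDDNode | None = None
    second_layer: SVC | None = None
    use_second_layer: bool = False
    artifacts: EncoderArtifacts = field(default_factory=EncoderArtifacts)
    seed: int = 0
    version: str = __version__
    training_keys: set = field(default_factory=set)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def train_single(
    pos_fragments: Sequence[SequenceFragment],
    neg_fragments: Sequence[SequenceFragment],
    scheme: str = "binary",
    params: SVMParams = SVMParams(),
    artifacts: EncoderArtifacts | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
    seed: int = 0,
) -> ModelBundle:
    """One RBF-SVM on all positives vs the (balanced) negative sample."""
    if abs(len(pos_fragments) - len(neg_fragments)) > 0.2 * max(
        len(pos_fragments), len(neg_fragments)
    ):
        logger.warning(
            "training classes are imbalanced (%d vs %d)",
            len(pos_fragments),
            len(neg_fragments),
        )
    artifacts = artifacts or EncoderArtifacts()
    X = np.vstack(
        [
            encode_fragments(pos_fragments, scheme, artifacts, proteins),
            encode_fragments(neg_fragments, scheme, artifacts, proteins),
        ]
    )
    y = np.concatenate(
        [np.ones(len(pos_fragments), dtype=int), np.zeros(len(neg_fragments), dtype=int)]
    )
    clf = _fit_svc(X, y, params, seed)
    keys = {(f.protein_id, f.position) for f in list(pos_fragments) + list(neg_fragments)}
    return ModelBundle(
        mode="single",
        scheme=scheme,
        models={0: clf},
        leaf_params={0: params},
        artifacts=artifacts,
        seed=seed,
        training_keys=keys,
    )


def train_mdd_clustered(
    pos_fragments: Sequence[SequenceFragment],
    neg_fragments: Sequence[SequenceFragment],
    mdd_cfg: MDDConfig = MDDConfig(),
    scheme: str = "binary",
    params: SVMParams | None = SVMParams(),
    grid: Sequence[SVMParams] | None = None,
    artifacts: EncoderArtifacts | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Per-motif-subgroup SVMs over an MDD tree built on the positives.

    Negatives are routed down the positive-trained tree by their own
    residues; each leaf is balanced to its positive count by a seeded
    subsample of its routed negatives (topped up from the global pool
    when a leaf attracts too few).  With *grid* given, each leaf runs
    its own (C, gamma) search; otherwise the fixed *params* are used.
    """
    artifacts = artifacts or EncoderArtifacts()
    tree = mdd_cluster(pos_fragments, mdd_cfg)
    leaves = tree.leaves()
    routed: dict[int, list[SequenceFragment]] = {leaf.leaf_id: [] for leaf in leaves}
    for frag in neg_fragments:
        routed[route_fragment(tree, frag)].append(frag)
    rng = np.random.default_rng(seed)
    models: dict[int, SVC] = {}
    leaf_params: dict[int, SVMParams] = {}
    for leaf in leaves:
        need = leaf.size
        pool = routed[leaf.leaf_id]
        if len(pool) >= need:
            idx = sorted(rng.choice(len(pool), size=need, replace=False).tolist())
            negs = [pool[i] for i in idx]
        else:
            if not pool:
                logger.warning(
                    "leaf %d attracted no negatives; sampling the global pool",
                    leaf.leaf_id,
                )
            negs = list(pool)
            pool_set = set(pool)
            remaining = [f for f in neg_fragments if f not in pool_set]
            extra = min(need - len(negs), len(remaining))
            if extra > 0:
                idx = sorted(rng.choice(len(remaining), size=extra, replace=False).tolist())
                negs += [remaining[i] for i in idx]
        X_pos = encode_fragments(leaf.fragments, scheme, artifacts, proteins)
        X_neg = encode_fragments(negs, scheme, artifacts, proteins)
        if grid is not None:
            p = grid_search(X_pos, X_neg, grid, seed=seed)
        else:
            p = params or SVMParams()
        y = np.concatenate([np.ones(len(X_pos), dtype=int), np.zeros(len(X_neg), dtype=int)])
        models[leaf.leaf_id] = _fit_svc(np.vstack([X_pos, X_neg]), y, p, seed)
        leaf_params[leaf.leaf_id] = p
    keys = {(f.protein_id, f.position) for f in list(pos_fragments) + list(neg_fragments)}
    return ModelBundle(
        mode="mdd_clustered",
        scheme=scheme,
        models=models,
        leaf_params=leaf_params,
        tree=tree,
        artifacts=artifacts,
        seed=seed,
        training_keys=keys,
    )


def _score_fragments(
    bundle: ModelBundle,
    fragments: Sequence[SequenceFragment],
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(probability, leaf id) for each fragment under *bundle*."""
    X = encode_fragments(fragments, bundle.scheme, bundle.artifacts, proteins)
    n = len(fragments)
    probs = np.zeros(n)
    leaf_ids = np.zeros(n, dtype=int)
    if bundle.mode == "single":
        probs = _proba_positive(bundle.models[0], X)
    else:
        leaf_ids = np.array(
            [route_fragment(bundle.tree, f) for f in fragments], dtype=int
        )
        if bundle.use_second_layer and bundle.second_layer is not None:
            stacked = _stacking_features(bundle, X)
            probs = _proba_positive(bundle.second_layer, stacked)
        else:
            for leaf_id in np.unique(leaf_ids):
                mask = leaf_ids == leaf_id
                probs[mask] = _proba_positive(bundle.models[int(leaf_id)], X[mask])
    return probs, leaf_ids


def _stacking_features(bundle: ModelBundle, X: np.ndarray) -> np.ndarray:
    cols = [
        _proba_positive(bundle.models[leaf_id], X)
        for leaf_id in sorted(bundle.models)
    ]
    return np.column_stack(cols)


def train_second_layer(
    bundle: ModelBundle,
    pos_fragments: Sequence[SequenceFragment],
    neg_fragments: Sequence[SequenceFragment],
    params: SVMParams = SVMParams(),
    proteins: Mapping[str, ProteinRecord] | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Fit a stacking SVM over the per-leaf probability vectors.

    The stacking input of a fragment has one dimension per MDD leaf.
    The fitted model is stored on the bundle but stays disabled until
    ``bundle.use_second_layer`` is set.
    """
    X = np.vstack(
        [
            encode_fragments(pos_fragments, bundle.scheme, bundle.artifacts, proteins),
            encode_fragments(neg_fragments, bundle.scheme, bundle.artifacts, proteins),
        ]
    )
    y = np.concatenate(
        [np.ones(len(pos_fragments), dtype=int), np.zeros(len(neg_fragments), dtype=int)]
    )
    stacked = _stacking_features(bundle, X)
    bundle.second_layer = _fit_svc(stacked, y, params, seed)
    return bundle


def predict(
    bundle: ModelBundle,
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    sites: Sequence[SiteRecord] | None = None,
    window: WindowConfig | None = None,
    threshold: float = 0.5,
) -> list[dict]:
    """Score candidate sites (all S/T positions by default).

    Returns one record per site: protein_id, position, residue,
    probability, predicted label (probability >= threshold counts as
    positive) and, in clustered mode, the leaf id / motif tag.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    cfg = window or bundle.artifacts.window
    if sites is None:
        sites = [
            SiteRecord(p.id, i, ch, "unknown")
            for p in proteins.values()
            for i, ch in enumerate(p.sequence, start=1)
            if ch in ("S", "T")
        ]
    fragments = [
        extract_fragment(proteins[s.protein_id], s.position, cfg, s.label)
        for s in sites
    ]
    probs, leaf_ids = _score_fragments(bundle, fragments, proteins)
    out = []
    for s, frag, prob, leaf_id in zip(sites, fragments, probs, leaf_ids):
        rec = {
            "protein_id": s.protein_id,
            "position": s.position,
            "residue": s.residue,
            "probability": float(prob),
            "label": "positive" if prob >= threshold else "negative",
        }
        if bundle.mode == "mdd_clustered":
            rec["leaf_id"] = int(leaf_id)
            rec["motif_tag"] = f"OG{leaf_id + 1}"
        out.append(rec)
    return out


def _tally(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return tp, fp, tn, fn


def cross_validate(
    pos_fragments: Sequence[SequenceFragment],
    neg_fragments: Sequence[SequenceFragment],
    k: int = 5,
    scheme: str = "binary",
    mode: str = "single",
    mdd_cfg: MDDConfig = MDDConfig(),
    params: SVMParams | None = SVMParams(),
    grid: Sequence[SVMParams] | None = None,
    artifacts: EncoderArtifacts | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
    seed: int = 0,
) -> EvalMetrics:
    """Stratified k-fold cross-validation, confusion counts pooled.

    Each fold trains a fresh model (including, in clustered mode, a
    fresh MDD tree on the fold's training positives) and scores the held
    -out fold; the k confusion matrices are summed and the metrics are
    computed once from the pooled counts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fragments = list(pos_fragments) + list(neg_fragments)
    y = np.concatenate(
        [np.ones(len(pos_fragments), dtype=int), np.zeros(len(neg_fragments), dtype=int)]
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_pos = [fragments[i] for i in train_idx if y[i] == 1]
        train_neg = [fragments[i] for i in train_idx if y[i] == 0]
        test = [fragments[i] for i in test_idx]
        if mode == "single":
            p = params or SVMParams()
            if grid is not None:
                art = artifacts or EncoderArtifacts()
                p = grid_search(
                    encode_fragments(train_pos, scheme, art, proteins),
                    encode_fragments(train_neg, scheme, art, proteins),
                    grid,
                    seed=seed,
                )
            bundle = train_single(
                train_pos, train_neg, scheme, p, artifacts, proteins, seed
            )
        elif mode == "mdd_clustered":
            bundle = train_mdd_clustered(
                train_pos,
                train_neg,
                mdd_cfg,
                scheme,
                params,
                grid,
                artifacts,
                proteins,
                seed,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        probs, _ = _score_fragments(bundle, test, proteins)
        pred = (probs >= 0.5).astype(int)
        dtp, dfp, dtn, dfn = _tally(pred, y[test_idx])
        tp, fp, tn, fn = tp + dtp, fp + dfp, tn + dtn, fn + dfn
    return compute_metrics(tp, fp, tn, fn)


def evaluate_independent(
    bundle: ModelBundle,
    test_fragments: Sequence[SequenceFragment],
    proteins: Mapping[str, ProteinRecord] | None = None,
    threshold: float = 0.5,
) -> EvalMetrics:
    """Metrics on an independent test set at its natural class ratio.

    Overlap with the bundle's training sites (same protein and position)
    is reported as a warning listing the offenders, never silently.
    """
    if not test_fragments:
        raise ValueError("empty test set")
    overlap = [
        f
        for f in test_fragments
        if (f.protein_id, f.position) in bundle.training_keys
    ]
    if overlap:
        logger.warning(
            "independent test overlaps training at %d sites: %s",
            len(overlap),
            [(f.protein_id, f.position) for f in overlap[:10]],
        )
    probs, _ = _score_fragments(bundle, test_fragments, proteins)
    truth = np.array(
        [1 if f.label == "positive" else 0 for f in test_fragments], dtype=int
    )
    pred = (probs >= threshold).astype(int)
    return compute_metrics(*_tally(pred, truth))
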