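"""Class balancing by K-means subsampling of the negative fragment pool.

Unmodified S/T windows outnumber modified ones by roughly 70:1, so
training on the raw data would bias the classifier.  The pool of
negative windows is clustered into K groups (K = the number of
positives) and each cluster contributes its member closest to the
cluster centroid, yielding K diverse, real (non-synthetic) negative
windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from glycmotif.encoders import EncoderArtifacts, encode_fragments
from glycmotif.seqdata import SequenceFragment


@dataclass(frozen=True)
class SamplingConfig:
    """K-means subsampling settings.

    ``k`` is the number of negatives to keep (the number of positives in
    a balanced design).  Clustering runs on the fragments encoded under
    ``feature_scheme`` (binary by default: cheap and independent of any
    training-derived matrices).
    """

    k: int
    feature_scheme: str = "binary"
    seed: int = 0
    max_iter: int = 300
    n_init: int = 1


def kmeans_subsample(
    negative_fragments: Sequence[SequenceFragment],
    cfg: SamplingConfig,
    artifacts: EncoderArtifacts | None = None,
) -> list[SequenceFragment]:
    """Select ``cfg.k`` representative negative fragments.

    One member per cluster, the one nearest its centroid (Euclidean;
    ties resolved to the lowest input index).  In the rare case of an
    empty cluster the shortfall is refilled with the unselected
    fragments nearest the grand centroid.  Deterministic given the seed.
    """
    n = len(negative_fragments)
    if cfg.k > n:
        raise ValueError(f"k={cfg.k} exceeds pool size {n}")
    if cfg.k == n:
        return list(negative_fragments)
    X = encode_fragments(negative_fragments, cfg.feature_scheme, artifacts)
    km = KMeans(
        n_clusters=cfg.k,
        random_state=cfg.seed,
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
    ).fit(X)
    selected: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for c in range(cfg.k):
        members = np.flatnonzero(km.labels_ == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        best = members[int(np.argmin(d))]  # argmin -> lowest index on ties
        selected.append(int(best))
        taken[best] = True
    if len(selected) < cfg.k:  # empty clusters: refill near the grand centroid
        grand = X.mean(axis=0)
        d = np.linalg.norm(X - grand, axis=1)
        for idx in np.argsort(d, kind="stable"):
            if len(selected) == cfg.k:
                break
            if not taken[idx]:
                selected.append(int(idx))
                taken[idx] = True
    selected.sort()
    return [negative_fragments[i] for i in selected]


def random_subsample(
    negative_fragments: Sequence[SequenceFragment], k: int, seed: int = 0
) -> list[SequenceFragment]:
    """Plain seeded random baseline (no clustering)."""
    n = len(negative_fragments)
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False).tolist())
    return [negative_fragments[i] for i in idx]
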