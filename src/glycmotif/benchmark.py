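"""Seeded benchmark studies on the synthetic motif data.

Three study harnesses shared by the test suite and the acceptance
script:

* motif recovery — does the MDD decomposition of the planted 3-class
  benchmark yield leaves whose dominant (offset, group) signatures
  match all three planted anchors?
* null calibration — on group-independent random windows, is the rate
  of position pairs flagged significant consistent with the nominal
  p < 0.005 level?
* direction study — does the MDD-clustered model beat the single model
  in pooled cross-validated balanced accuracy, seed over seed?

Problem sizes are chosen to make each study run in minutes on one CPU:
375 positives (125 per class), a negative pool of 8x the positives for
K-means subsampling, and fixed RBF parameters shared by both model
modes in the direction study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glycmotif.classifier import SVMParams, cross_validate
from glycmotif.mdd import (
    DEFAULT_SCHEME,
    MDDConfig,
    MDDNode,
    ResidueGroupScheme,
    dependence_map,
    mdd_cluster,
)
from glycmotif.sampling import SamplingConfig, kmeans_subsample
from glycmotif.seqdata import WindowConfig
from glycmotif.simulate import (
    GeneratorConfig,
    MotifSpec,
    make_dataset,
    random_fragments,
)

#: Fallback RBF parameters (binary features) when no grid search is run.
BENCH_PARAMS = SVMParams(C=8.0, gamma=2.0**-6)


def benchmark_config(seed: int, neg_ratio: int = 8) -> GeneratorConfig:
    """The 3-class benchmark conditions at the stated scale."""
    return GeneratorConfig(seed=seed, neg_pool_size=neg_ratio * 375)


def leaf_signature(
    leaf: MDDNode,
    scheme: ResidueGroupScheme = DEFAULT_SCHEME,
    window: WindowConfig = WindowConfig(),
    background_group_freqs: np.ndarray | None = None,
) -> tuple[int, int]:
    """The (offset, group) with the strongest enrichment in a leaf.

    For every non-center offset and group, the observed group frequency
    among the leaf's members is compared with its background expectation
    by a one-proportion z score; the maximal z wins.  On the benchmark a
    leaf dominated by one planted class reports that class's anchor.
    """
    exp = (
        background_group_freqs
        if background_group_freqs is not None
        else scheme.background_group_freqs()
    )
    N = leaf.size
    best = None
    best_key = None
    for off in range(-window.n, window.n + 1):
        if off == 0:
            continue
        counts = np.zeros(len(scheme.groups))
        observed = 0
        for frag in leaf.fragments:
            gi = scheme.group_of(frag.at_offset(off))
            if gi is not None:
                counts[gi] += 1
                observed += 1
        if observed == 0:
            continue
        freqs = counts / observed
        for gi in range(len(scheme.groups)):
            se = np.sqrt(exp[gi] * (1 - exp[gi]) / observed)
            z = (freqs[gi] - exp[gi]) / se
            key = (-z, abs(off), 0 if off < 0 else 1, gi)
            if best_key is None or key < best_key:
                best_key = key
                best = (off, gi)
    return best


def planted_anchors(
    motifs: tuple[MotifSpec, ...], scheme: ResidueGroupScheme = DEFAULT_SCHEME
) -> set[tuple[int, int]]:
    """The (offset, group index) pairs the generator planted as anchors."""
    return {
        (spec.anchor[0], scheme.group_of(spec.anchor[1][0])) for spec in motifs
    }


def motif_recovery_trial(
    seed: int, mdd_cfg: MDDConfig = MDDConfig()
) -> tuple[bool, set[tuple[int, int]]]:
    """One seeded benchmark run; True when all planted anchors are
    recovered as dominant leaf signatures of the decomposition."""
    cfg = benchmark_config(seed)
    data = make_dataset(cfg)
    tree = mdd_cluster(data.pos_fragments, mdd_cfg)
    signatures = {
        leaf_signature(leaf, mdd_cfg.scheme, cfg.window) for leaf in tree.leaves()
    }
    wanted = planted_anchors(cfg.motifs, mdd_cfg.scheme)
    return wanted <= signatures, signatures


def motif_recovery_rate(n_seeds: int = 20, base_seed: int = 0) -> float:
    hits = sum(motif_recovery_trial(base_seed + s)[0] for s in range(n_seeds))
    return hits / n_seeds


def null_significant_rate(
    min_pairs: int = 1000,
    seed: int = 0,
    n_fragments: int = 375,
    mdd_cfg: MDDConfig = MDDConfig(),
) -> tuple[float, int]:
    """Fraction of position pairs flagged significant on null data.

    Generates independent background-only fragment sets until at least
    *min_pairs* unordered position pairs have been tested; returns the
    observed significant-pair rate and the number of pairs tested.
    Should be consistent with the nominal level of the threshold.
    """
    rng = np.random.default_rng(seed)
    offs = mdd_cfg.offsets()
    pairs_per_set = len(offs) * (len(offs) - 1) // 2
    tested = significant = 0
    gen_cfg = GeneratorConfig(seed=seed)
    while tested < min_pairs:
        frags = random_fragments(n_fragments, gen_cfg, rng)
        dmap = dependence_map(frags, mdd_cfg)
        for a_idx, i in enumerate(offs):
            for j in offs[a_idx + 1 :]:
                tested += 1
                if dmap.loc[i, j] > mdd_cfg.chi2_threshold:
                    significant += 1
    return significant / tested, tested


@dataclass
class DirectionResult:
    """Per-seed balanced accuracies of the two model modes."""

    single: list[float]
    clustered: list[float]

    @property
    def clustered_wins(self) -> float:
        """Fraction of seeds where clustered >= single."""
        wins = sum(c >= s for s, c in zip(self.single, self.clustered))
        return wins / len(self.single)


def direction_trial(
    seed: int,
    mdd_cfg: MDDConfig = MDDConfig(),
    params: SVMParams | None = None,
    scheme: str = "binary",
    k: int = 5,
) -> tuple[float, float]:
    """Pooled 5-fold CV balanced accuracy of single vs clustered models.

    Negatives are balanced to the positives once, globally, by K-means
    subsampling before fold assignment.  Unless fixed *params* are
    given, a reduced (C, gamma) grid search on the balanced data picks
    the RBF parameters, which are then shared by both modes so the
    comparison isolates the effect of the motif clustering itself.
    """
    cfg = benchmark_config(seed)
    data = make_dataset(cfg)
    negs = kmeans_subsample(
        data.neg_fragments,
        SamplingConfig(k=len(data.pos_fragments), seed=seed),
    )
    if params is None:
        from glycmotif.classifier import SMALL_GRID, grid_search
        from glycmotif.encoders import encode_fragments

        params = grid_search(
            encode_fragments(data.pos_fragments, scheme),
            encode_fragments(negs, scheme),
            SMALL_GRID,
            seed=seed,
        )
    single = cross_validate(
        data.pos_fragments, negs, k=k, scheme=scheme, mode="single",
        params=params, seed=seed,
    )
    clustered = cross_validate(
        data.pos_fragments, negs, k=k, scheme=scheme, mode="mdd_clustered",
        mdd_cfg=mdd_cfg, params=params, seed=seed,
    )
    return single.balanced_accuracy, clustered.balanced_accuracy


def direction_study(n_seeds: int = 20, base_seed: int = 0) -> DirectionResult:
    singles, clusters = [], []
    for s in range(n_seeds):
        sb, cb = direction_trial(base_seed + s)
        singles.append(sb)
        clusters.append(cb)
    return DirectionResult(singles, clusters)
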