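"""Maximal dependence decomposition (MDD) of substrate sequence windows.

Aligned positive windows are recursively partitioned into motif subgroups.
At each node the dependence between every pair of window positions is
measured with a chi-square test on a 5x5 contingency table of chemically
grouped residues; the position with the strongest significant dependence
on the rest of the window, together with its dominant residue group,
defines a binary split (group present / absent at that position).
Recursion stops when a node is smaller than the minimum cluster size or
no position pair reaches the significance threshold (by default the
p < 0.005 critical value for 16 degrees of freedom, 34.3).

The chi-square statistic for positions ``A_i`` and ``A_j`` is

    chi2(A_i, A_j) = sum_{m=1..5} sum_{n=1..5} (X_mn - E_mn)^2 / E_mn

where ``X_mn`` counts windows with a group-*m* residue at ``A_i`` and a
group-*n* residue at ``A_j``, and ``E_mn = X_mR * X_Cn / X`` is the
expected count under independence from the row/column marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycmotif.seqdata import AMINO_ACIDS, SequenceFragment, WindowConfig

GROUP_NAMES = ("acidic", "polar", "basic", "aromatic", "hydrophobic")
N_GROUPS = len(GROUP_NAMES)


@dataclass(frozen=True)
class ResidueGroupScheme:
    """Partition of the 20 amino acids into 5 chemical groups.

    The default assigns: acidic {D,E}; polar {S,T,G,N,Q,C};
    basic {K,R,H}; aromatic {F,W,Y}; hydrophobic {A,V,L,I,P,M}.
    Serine/threonine/glycine are polar and proline/valine/alanine are
    hydrophobic, matching the grouping behind the discovered motifs.
    """

    groups: tuple[tuple[str, ...], ...] = (
        ("D", "E"),
        ("S", "T", "G", "N", "Q", "C"),
        ("K", "R", "H"),
        ("F", "W", "Y"),
        ("A", "V", "L", "I", "P", "M"),
    )

    def __post_init__(self) -> None:
        if len(self.groups) != N_GROUPS:
            raise ValueError("scheme must define exactly 5 groups")
        covered = [aa for grp in self.groups for aa in grp]
        if sorted(covered) != sorted(AMINO_ACIDS):
            raise ValueError("scheme must cover each of the 20 amino acids once")
        if any(not grp for grp in self.groups):
            raise ValueError("all 5 groups must be non-empty")

    @property
    def mapping(self) -> dict[str, int]:
        return {aa: gi for gi, grp in enumerate(self.groups) for aa in grp}

    def group_of(self, residue: str) -> int | None:
        """0-based group index, or None for pad/unknown characters."""
        return self.mapping.get(residue)

    def background_group_freqs(self, residue_freqs: dict[str, float] | None = None) -> np.ndarray:
        """Expected group frequencies under a residue background (uniform default)."""
        freqs = residue_freqs or {aa: 1 / 20 for aa in AMINO_ACIDS}
        return np.array([sum(freqs[aa] for aa in grp) for grp in self.groups])


DEFAULT_SCHEME = ResidueGroupScheme()


def assign_group(residue: str, scheme: ResidueGroupScheme = DEFAULT_SCHEME) -> int:
    """0-based group index of *residue* under *scheme*.

    Pad (``-``) and unknown (``X``) characters carry no group and raise;
    tally code should skip them via :meth:`ResidueGroupScheme.group_of`.
    """
    gi = scheme.group_of(residue)
    if gi is None:
        raise ValueError(f"residue {residue!r} has no chemical group")
    return gi


@dataclass(frozen=True)
class MDDConfig:
    """Knobs of the recursive decomposition.

    ``chi2_threshold`` defaults to the upper 0.005 critical value of the
    chi-square distribution with (5-1)*(5-1) = 16 degrees of freedom,
    34.3 to one decimal.  ``min_cluster_size`` is the smallest node that
    is still considered for splitting.
    """

    chi2_threshold: float = 34.3
    significance: float = 0.005
    dof: int = (N_GROUPS - 1) * (N_GROUPS - 1)
    min_cluster_size: int = 150
    scheme: ResidueGroupScheme = DEFAULT_SCHEME
    exclude_center: bool = True
    window: WindowConfig = WindowConfig()

    def __post_init__(self) -> None:
        if self.chi2_threshold <= 0:
            raise ValueError("chi2_threshold must be positive")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")

    def offsets(self) -> list[int]:
        n = self.window.n
        offs = [o for o in range(-n, n + 1)]
        if self.exclude_center:
            offs.remove(0)
        return offs


@dataclass
class ContingencyTable:
    """5x5 grouped-residue co-occurrence counts between offsets i and j."""

    i: int
    j: int
    counts: np.ndarray  # (5, 5) integer counts X_mn

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def expected(self) -> np.ndarray:
        """E_mn = X_mR * X_Cn / X (zero marginals give zero expecteds)."""
        total = self.total
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return np.outer(self.row_sums, self.col_sums) / total


def build_contingency(
    fragments: Sequence[SequenceFragment],
    i: int,
    j: int,
    scheme: ResidueGroupScheme = DEFAULT_SCHEME,
) -> ContingencyTable:
    """Tally group co-occurrence between window offsets *i* and *j*.

    Fragments with a pad or unknown character at either offset are
    excluded from the table (they carry no group).
    """
    if i == j:
        raise ValueError("offsets i and j must differ")
    if not fragments:
        raise ValueError("no fragments to tally")
    counts = np.zeros((N_GROUPS, N_GROUPS), dtype=np.int64)
    for frag in fragments:
        gi = scheme.group_of(frag.at_offset(i))
        gj = scheme.group_of(frag.at_offset(j))
        if gi is None or gj is None:
            continue
        counts[gi, gj] += 1
    return ContingencyTable(i, j, counts)


def chi_square(table: ContingencyTable) -> float:
    """The grouped-residue chi-square statistic of *table*.

    Cells with zero expected count (forced by zero marginals) contribute
    nothing; such cells necessarily have zero observed count.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    expected = table.expected
    mask = expected > 0
    diff = table.counts[mask] - expected[mask]
    return float(np.sum(diff * diff / expected[mask]))


def group_contributions(table: ContingencyTable) -> np.ndarray:
    """Per-row (group at offset i) chi-square contributions, length 5."""
    expected = table.expected
    out = np.zeros(N_GROUPS)
    for m in range(N_GROUPS):
        mask = expected[m] > 0
        diff = table.counts[m, mask] - expected[m, mask]
        out[m] = np.sum(diff * diff / expected[m, mask])
    return out


def chi2_critical(p: float = 0.005, dof: int = 16) -> float:
    """Upper-tail chi-square critical value (e.g. 34.27 for p=0.005, df=16)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return float(stats.chi2.isf(p, dof))


def dependence_map(
    fragments: Sequence[SequenceFragment], cfg: MDDConfig = MDDConfig()
) -> pd.DataFrame:
    """Chi-square statistic for every ordered pair of window offsets.

    Returns a symmetric DataFrame indexed by offsets (center excluded by
    default); the diagonal is NaN.  Pairs whose table is empty (all
    fragments padded at one offset) are NaN as well.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    offs = cfg.offsets()
    mat = pd.DataFrame(np.nan, index=offs, columns=offs, dtype=float)
    for a_idx, i in enumerate(offs):
        for j in offs[a_idx + 1 :]:
            table = build_contingency(fragments, i, j, cfg.scheme)
            if table.total == 0:
                continue
            val = chi_square(table)
            mat.loc[i, j] = val
            mat.loc[j, i] = val
    return mat


def max_dependence_split(
    fragments: Sequence[SequenceFragment], cfg: MDDConfig = MDDConfig()
) -> tuple[int, int] | None:
    """The (offset, group index) pair of maximal dependence, or None.

    The split position is the offset maximizing the sum of significant
    chi-square statistics against all other offsets; the split group is
    the row (group at that offset) with the largest summed chi-square
    contribution over those significant partner tables.  Ties break
    deterministically: smaller |offset|, then upstream (negative) before
    downstream, then lower group index.
    """
    if len(fragments) < 2:
        return None
    offs = cfg.offsets()
    dmap = dependence_map(fragments, cfg)
    row_sums: dict[int, float] = {}
    partners: dict[int, list[int]] = {}
    for i in offs:
        sig = [
            j
            for j in offs
            if j != i
            and not np.isnan(dmap.loc[i, j])
            and dmap.loc[i, j] > cfg.chi2_threshold
        ]
        if sig:
            row_sums[i] = float(sum(dmap.loc[i, j] for j in sig))
            partners[i] = sig
    if not row_sums:
        return None

    def pos_key(i: int) -> tuple[float, int, int]:
        # maximize row sum; ties -> smaller |offset|, upstream first
        return (-row_sums[i], abs(i), 0 if i < 0 else 1)

    i_star = min(row_sums, key=pos_key)
    contrib = np.zeros(N_GROUPS)
    for j in partners[i_star]:
        contrib += group_contributions(build_contingency(fragments, i_star, j, cfg.scheme))
    m_star = int(np.argmax(contrib))  # argmax takes the lowest index on ties
    return i_star, m_star


@dataclass
class MDDNode:
    """A node of the recursive decomposition tree.

    Internal nodes carry a ``split`` (offset, group index) and two
    children: ``present`` (fragments with a residue of the split group at
    the split offset) and ``absent``.  Leaves carry a depth-first
    ``leaf_id`` starting at 0.
    """

    fragments: list[SequenceFragment]
    depth: int = 0
    split: tuple[int, int] | None = None
    present: "MDDNode | None" = None
    absent: "MDDNode | None" = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def size(self) -> int:
        return len(self.fragments)

    def leaves(self) -> list["MDDNode"]:
        if self.is_leaf:
            return [self]
        return self.present.leaves() + self.absent.leaves()

    def splits(self) -> list[tuple[int, int]]:
        """All (offset, group index) splits in the subtree, preorder."""
        if self.is_leaf:
            return []
        return [self.split] + self.present.splits() + self.absent.splits()


def _group_present(
    frag: SequenceFragment, offset: int, group: int, scheme: ResidueGroupScheme
) -> bool:
    """Pad/unknown at the offset counts as 'absent'."""
    return scheme.group_of(frag.at_offset(offset)) == group


def mdd_cluster(
    fragments: Sequence[SequenceFragment], cfg: MDDConfig = MDDConfig()
) -> MDDNode:
    """Recursively partition *fragments* into motif subgroups.

    A node is split only if it holds at least ``min_cluster_size``
    fragments, a significant maximal-dependence split exists, and the
    split sends at least one fragment to each branch.  Leaves are
    numbered depth-first (present branch first).
    """
    if not fragments:
        raise ValueError("no fragments to cluster")

    def build(frags: list[SequenceFragment], depth: int) -> MDDNode:
        node = MDDNode(fragments=frags, depth=depth)
        if len(frags) < cfg.min_cluster_size:
            return node
        split = max_dependence_split(frags, cfg)
        if split is None:
            return node
        offset, group = split
        present = [f for f in frags if _group_present(f, offset, group, cfg.scheme)]
        absent = [f for f in frags if not _group_present(f, offset, group, cfg.scheme)]
        if not present or not absent:
            return node  # degenerate split routes everything one way
        node.split = split
        node.present = build(present, depth + 1)
        node.absent = build(absent, depth + 1)
        return node

    root = build(list(fragments), 0)
    for k, leaf in enumerate(root.leaves()):
        leaf.leaf_id = k
    attach_scheme(root, cfg.scheme)
    return root


def route_fragment(tree: MDDNode, fragment: SequenceFragment) -> int:
    """Leaf id reached by following the tree's splits on *fragment*.

    A pad or unknown character at a split offset routes to the absent
    branch.
    """
    scheme = _tree_scheme(tree)
    node = tree
    while not node.is_leaf:
        offset, group = node.split
        if _group_present(fragment, offset, group, scheme):
            node = node.present
        else:
            node = node.absent
    return node.leaf_id


_SCHEME_ATTR = "_scheme"


def _tree_scheme(tree: MDDNode) -> ResidueGroupScheme:
    return getattr(tree, _SCHEME_ATTR, DEFAULT_SCHEME)


def attach_scheme(tree: MDDNode, scheme: ResidueGroupScheme) -> MDDNode:
    setattr(tree, _SCHEME_ATTR, scheme)
    return tree


@dataclass
class PositionFrequencyMatrix:
    """Per-offset relative residue frequencies of a fragment set."""

    freqs: np.ndarray  # (2n+1, 20), rows over offsets -n..+n
    n_fragments: int
    offsets: list[int]
    residues: str = AMINO_ACIDS

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.freqs, index=self.offsets, columns=list(self.residues))
        df.index.name = "offset"
        df.to_csv(path, sep="\t", float_format="%.6f")


def export_pfm(
    node: MDDNode, window: WindowConfig = WindowConfig()
) -> PositionFrequencyMatrix:
    """Relative frequencies over non-pad, non-X residues per offset.

    Rows where only pads/unknowns were observed are all-zero; every other
    row sums to 1.  Suitable as input to sequence-logo renderers.
    """
    if not node.fragments:
        raise ValueError("node has no fragments")
    n = window.n
    offsets = list(range(-n, n + 1))
    counts = np.zeros((len(offsets), 20))
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    for frag in node.fragments:
        for r, off in enumerate(offsets):
            ch = frag.at_offset(off)
            k = aa_index.get(ch)
            if k is not None:
                counts[r, k] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return PositionFrequencyMatrix(freqs, len(node.fragments), offsets)


def position_difference(
    pos_fragments: Sequence[SequenceFragment],
    neg_fragments: Sequence[SequenceFragment],
    window: WindowConfig = WindowConfig(),
) -> pd.DataFrame:
    """Per-(offset, residue) frequency difference with a two-proportion z.

    ``difference = freq_pos - freq_neg``; the z statistic uses the pooled
    proportion: z = diff / sqrt(p*(1-p)*(1/N1 + 1/N2)).  No multiple-
    testing correction is applied; the caller decides.  Rows are
    (offset, residue) pairs.
    """
    if not pos_fragments or not neg_fragments:
        raise ValueError("both fragment sets must be non-empty")
    pfm_pos = export_pfm(MDDNode(list(pos_fragments)), window)
    pfm_neg = export_pfm(MDDNode(list(neg_fragments)), window)
    n1, n2 = len(pos_fragments), len(neg_fragments)
    rows = []
    for r, off in enumerate(pfm_pos.offsets):
        for k, aa in enumerate(AMINO_ACIDS):
            p1 = pfm_pos.freqs[r, k]
            p2 = pfm_neg.freqs[r, k]
            pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            z = (p1 - p2) / se if se > 0 else 0.0
            rows.append(
                {"offset": off, "residue": aa, "difference": p1 - p2, "z": z}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tree serialization


def tree_to_dict(tree: MDDNode, scheme: ResidueGroupScheme = DEFAULT_SCHEME) -> dict:
    def encode(node: MDDNode) -> dict:
        d: dict = {"size": node.size, "depth": node.depth}
        if node.is_leaf:
            d["leaf_id"] = node.leaf_id
            d["fragment_ids"] = [
                f"{f.protein_id}:{f.position}" for f in node.fragments
            ]
        else:
            offset, group = node.split
            d["split"] = {"offset": offset, "group": GROUP_NAMES[group]}
            d["present"] = encode(node.present)
            d["absent"] = encode(node.absent)
        return d

    return {
        "groups": {name: list(grp) for name, grp in zip(GROUP_NAMES, scheme.groups)},
        "tree": encode(tree),
    }


def save_tree(tree: MDDNode, path, scheme: ResidueGroupScheme = DEFAULT_SCHEME) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree, scheme), fh, indent=1, sort_keys=True)
        fh.write("\n")
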