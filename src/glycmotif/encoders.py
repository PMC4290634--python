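"""Numeric feature encodings of sequence windows.

Six schemes are provided for an ``2n+1`` window (220/20/400/11/400/11
dimensions at the default n=5):

* ``binary`` — orthogonal one-hot coding per position, glycine first;
* ``aac`` — amino-acid composition over the window;
* ``aapc`` — ordered adjacent amino-acid-pair composition;
* ``pwm`` — per-offset relative-frequency lookup in a position weight
  matrix built from the positive training windows (20 residues plus a
  terminal-signal column for window positions beyond the sequence ends);
* ``pssm`` — a 400-dimensional transform of a per-protein PSI-BLAST
  position-specific scoring matrix: window rows are pooled by residue
  type into a 20x20 matrix, scaled by the window length and squashed
  through a logistic sigmoid;
* ``asa`` — predicted accessible-surface-area values of the window
  residues, min-max normalized over the dataset.

Pad positions carry zeros in the binary and ASA encodings and are
excluded from composition denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from glycmotif.seqdata import (
    AMINO_ACIDS,
    UNKNOWN,
    ProteinRecord,
    SequenceFragment,
    WindowConfig,
)

#: Fixed residue order of the one-hot coding: glycine is slot 1, alanine
#: slot 2, then the remaining residues in a chemical ordering.
RESIDUE_ORDER = "GAVLIPFMWSTCYNQDEKRH"
assert len(RESIDUE_ORDER) == 20 and set(RESIDUE_ORDER) == set(AMINO_ACIDS)

_IDX = {aa: k for k, aa in enumerate(RESIDUE_ORDER)}

#: PSI-BLAST ASCII matrix column order.
PSIBLAST_COLUMNS = "ARNDCQEGHILKMFPSTWYV"
_PSI_TO_ORDER = [PSIBLAST_COLUMNS.index(a) for a in RESIDUE_ORDER]

SCHEMES = ("binary", "aac", "aapc", "pwm", "pssm", "asa")


def scheme_dim(scheme: str, cfg: WindowConfig = WindowConfig()) -> int:
    w = cfg.length
    return {
        "binary": 20 * w,
        "aac": 20,
        "aapc": 400,
        "pwm": w,
        "pssm": 400,
        "asa": w,
    }[scheme]


def encode_binary(fragment: SequenceFragment) -> np.ndarray:
    """One-hot coding, 20 slots per window position (pads/X all-zero)."""
    w = len(fragment.window)
    vec = np.zeros(20 * w)
    for p, ch in enumerate(fragment.window):
        k = _IDX.get(ch)
        if k is not None:
            vec[20 * p + k] = 1.0
    return vec


def encode_aac(fragment: SequenceFragment) -> np.ndarray:
    """Amino-acid composition: counts / number of non-pad residues."""
    vec = np.zeros(20)
    total = 0
    for ch in fragment.window:
        k = _IDX.get(ch)
        if k is not None:
            vec[k] += 1
            total += 1
    if total:
        vec /= total
    return vec


def encode_aapc(fragment: SequenceFragment) -> np.ndarray:
    """Ordered adjacent-pair composition (400-dim).

    Pairs touching a pad or unknown character are not counted; the
    vector is normalized by the number of counted pairs.
    """
    vec = np.zeros(400)
    total = 0
    win = fragment.window
    for a, b in zip(win, win[1:]):
        ka, kb = _IDX.get(a), _IDX.get(b)
        if ka is None or kb is None:
            continue
        vec[20 * ka + kb] += 1
        total += 1
    if total:
        vec /= total
    return vec


@dataclass
class PositionWeightMatrix:
    """(2n+1) x 21 relative frequencies: 20 residues + 1 terminal signal."""

    weights: np.ndarray  # rows over offsets -n..+n; last column = pad
    n_fragments: int

    @property
    def window_length(self) -> int:
        return self.weights.shape[0]


def build_pwm(
    positive_fragments: Sequence[SequenceFragment],
    cfg: WindowConfig = WindowConfig(),
) -> PositionWeightMatrix:
    """Per-offset relative frequencies of the 21 symbols (residues + pad).

    Unknown (``X``) observations are skipped; each row is normalized over
    the symbols actually observed, so rows sum to 1.
    """
    if not positive_fragments:
        raise ValueError("need at least one fragment")
    w = cfg.length
    counts = np.zeros((w, 21))
    for frag in positive_fragments:
        if len(frag.window) != w:
            raise ValueError("fragment window length does not match config")
        for p, ch in enumerate(frag.window):
            if ch == UNKNOWN:
                continue
            k = _IDX.get(ch, 20)  # pad -> terminal column
            counts[p, k] += 1
    totals = counts.sum(axis=1, keepdims=True)
    weights = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return PositionWeightMatrix(weights, len(positive_fragments))


def encode_pwm(fragment: SequenceFragment, pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-offset lookup of the fragment's own symbol in the PWM (11-dim)."""
    if len(fragment.window) != pwm.window_length:
        raise ValueError("fragment and PWM window lengths differ")
    vec = np.zeros(pwm.window_length)
    for p, ch in enumerate(fragment.window):
        if ch == UNKNOWN:
            continue
        k = _IDX.get(ch, 20)
        vec[p] = pwm.weights[p, k]
    return vec


@dataclass
class PSSMProfile:
    """Per-protein position-specific scores: one row per residue.

    ``scores`` columns follow :data:`PSIBLAST_COLUMNS`.
    """

    protein_id: str
    residues: str
    scores: np.ndarray  # (L, 20)

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.residues), 20):
            raise ValueError(
                f"profile {self.protein_id!r}: scores shape {self.scores.shape} "
                f"does not match sequence length {len(self.residues)}"
            )


def read_pssm(path, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the ``-Q`` checkpoint dialect).

    The header line naming the 20 (or 40) score columns fixes the column
    order; only the first 20 (log-odds) columns are kept.
    """
    residues: list[str] = []
    rows: list[list[float]] = []
    columns: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if columns is None:
                letters = [p for p in parts if len(p) == 1 and p.isalpha()]
                if len(letters) >= 20:
                    columns = "".join(letters[:20])
                continue
            if parts[0].isdigit():
                if len(parts) < 22:
                    raise ValueError(f"{path}:{lineno}: truncated PSSM row")
                residues.append(parts[1])
                try:
                    rows.append([float(x) for x in parts[2:22]])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score field") from exc
    if columns is None or not rows:
        raise ValueError(f"{path}: no PSSM matrix found")
    scores = np.asarray(rows, dtype=float)
    # reorder columns into the canonical PSI-BLAST order
    order = [columns.index(aa) for aa in PSIBLAST_COLUMNS]
    scores = scores[:, order]
    pid = protein_id or str(path)
    return PSSMProfile(pid, "".join(residues), scores)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (round-trips read_pssm)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(PSIBLAST_COLUMNS) + "\n")
        for i, (aa, row) in enumerate(zip(profile.residues, profile.scores), 1):
            cells = " ".join(f"{v:6.2f}" for v in row)
            fh.write(f"{i:5d} {aa} {cells}\n")


def encode_pssm400(
    profile: PSSMProfile,
    protein: ProteinRecord,
    position: int,
    cfg: WindowConfig = WindowConfig(),
) -> np.ndarray:
    """400-dim PSSM feature of the window centered at *position* (1-based).

    The (2n+1) x 20 sub-matrix of the profile centered on the site
    (missing rows beyond the termini are zero) is pooled into a 20 x 20
    matrix by summing rows whose sequence letter is the same residue
    type, scaled by 1/(2n+1), passed through 1/(1+exp(-x)) elementwise
    and flattened.  Every output lies strictly in (0, 1).
    """
    if len(profile.residues) != len(protein.sequence):
        raise ValueError(
            f"profile length {len(profile.residues)} != protein length "
            f"{len(protein.sequence)} for {protein.id!r}"
        )
    w = cfg.length
    pooled = np.zeros((20, 20))
    for off in range(-cfg.n, cfg.n + 1):
        idx = position - 1 + off
        if not 0 <= idx < len(protein.sequence):
            continue  # terminal overhang: zero row, contributes nothing
        aa = protein.sequence[idx]
        r = _IDX.get(aa)
        if r is None:
            continue
        # profile columns -> canonical residue order used everywhere else
        pooled[r] += profile.scores[idx][_PSI_TO_ORDER]
    pooled /= w
    return (1.0 / (1.0 + np.exp(-pooled))).ravel()


def fallback_profile(
    positive_fragments: Sequence[SequenceFragment],
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.01,
    cfg: WindowConfig = WindowConfig(),
) -> np.ndarray:
    """Per-offset log-odds scores from the positive windows.

    ``log2((freq + pseudocount) / (background + pseudocount))`` for each
    (offset, residue); usable as a profile substitute where PSI-BLAST
    searches have not been run.  Columns follow :data:`RESIDUE_ORDER`.
    """
    if not positive_fragments:
        raise ValueError("need at least one fragment")
    bg = background or {aa: 1 / 20 for aa in AMINO_ACIDS}
    w = cfg.length
    counts = np.zeros((w, 20))
    totals = np.zeros(w)
    for frag in positive_fragments:
        for p, ch in enumerate(frag.window):
            k = _IDX.get(ch)
            if k is not None:
                counts[p, k] += 1
                totals[p] += 1
    freqs = np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0)
    bg_vec = np.array([bg[aa] for aa in RESIDUE_ORDER])
    return np.log2((freqs + pseudocount) / (bg_vec + pseudocount))


# ---------------------------------------------------------------------------
# accessible surface area


def read_asa_table(path) -> dict[tuple[str, int], float]:
    """Read a per-residue ASA TSV (protein_id, position, asa_value)."""
    table: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, pos, value = line.split("\t")
            table[(pid, int(pos))] = float(value)
    return table


@dataclass(frozen=True)
class ASANormalizer:
    """Dataset-wide min-max scaling to [0, 1] (constant data maps to 0)."""

    minimum: float
    maximum: float

    @classmethod
    def fit(cls, values: Iterable[float]) -> "ASANormalizer":
        values = list(values)
        if not values:
            raise ValueError("no ASA values to fit")
        return cls(min(values), max(values))

    def transform(self, value: float) -> float:
        span = self.maximum - self.minimum
        if span <= 0:
            return 0.0
        return (value - self.minimum) / span


def encode_asa(
    asa_table: Mapping[tuple[str, int], float],
    protein: ProteinRecord,
    position: int,
    cfg: WindowConfig = WindowConfig(),
    normalizer: ASANormalizer | None = None,
) -> np.ndarray:
    """Normalized ASA values of the window residues (pads are 0).

    Raises if any in-sequence window residue lacks an ASA value, listing
    the missing positions.
    """
    norm = normalizer or ASANormalizer.fit(asa_table.values())
    vec = np.zeros(cfg.length)
    missing = []
    for p, off in enumerate(range(-cfg.n, cfg.n + 1)):
        pos = position + off
        if not 1 <= pos <= len(protein.sequence):
            continue  # pad
        key = (protein.id, pos)
        if key not in asa_table:
            missing.append(pos)
            continue
        vec[p] = norm.transform(asa_table[key])
    if missing:
        raise ValueError(f"{protein.id}: missing ASA values at positions {missing}")
    return vec


# ---------------------------------------------------------------------------
# dispatcher


@dataclass
class EncoderArtifacts:
    """Training-derived objects a fitted model needs at predict time."""

    pwm: PositionWeightMatrix | None = None
    profiles: dict[str, PSSMProfile] = field(default_factory=dict)
    asa_table: dict[tuple[str, int], float] = field(default_factory=dict)
    asa_normalizer: ASANormalizer | None = None
    window: WindowConfig = field(default_factory=WindowConfig)


def encode_fragment(
    fragment: SequenceFragment,
    scheme: str,
    artifacts: EncoderArtifacts | None = None,
    protein: ProteinRecord | None = None,
) -> np.ndarray:
    """Encode one fragment under *scheme*, using *artifacts* where needed."""
    if scheme == "binary":
        return encode_binary(fragment)
    if scheme == "aac":
        return encode_aac(fragment)
    if scheme == "aapc":
        return encode_aapc(fragment)
    art = artifacts
    if scheme == "pwm":
        if art is None or art.pwm is None:
            raise ValueError("pwm scheme requires a trained PositionWeightMatrix")
        return encode_pwm(fragment, art.pwm)
    if scheme == "pssm":
        if art is None or fragment.protein_id not in art.profiles:
            raise ValueError(
                f"pssm scheme requires a profile for {fragment.protein_id!r}"
            )
        if protein is None:
            profile = art.profiles[fragment.protein_id]
            protein = ProteinRecord(fragment.protein_id, profile.residues)
        return encode_pssm400(
            art.profiles[fragment.protein_id], protein, fragment.position, art.window
        )
    if scheme == "asa":
        if art is None or not art.asa_table:
            raise ValueError("asa scheme requires an ASA table")
        if protein is None:
            raise ValueError("asa scheme requires the protein record")
        return encode_asa(
            art.asa_table, protein, fragment.position, art.window, art.asa_normalizer
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def encode_fragments(
    fragments: Sequence[SequenceFragment],
    scheme: str,
    artifacts: EncoderArtifacts | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> np.ndarray:
    """Stack encodings of *fragments* into an (N, D) matrix."""
    rows = []
    for frag in fragments:
        protein = proteins.get(frag.protein_id) if proteins else None
        rows.append(encode_fragment(frag, scheme, artifacts, protein))
    return np.asarray(rows)
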