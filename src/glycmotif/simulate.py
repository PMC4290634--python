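"""Synthetic proteins with planted O-GlcNAc-like motif classes.

The generator emulates the positional composition of real substrate
data: background proteins with i.i.d. residues, a set of S/T sites
planted with class-specific motif constraints, and companion ASA and
PSSM fixtures, so that every stage of the pipeline can be exercised
without external databases or search tools.

Each motif class has an anchor enrichment — by default the three
discovered motif classes: polar residues {S,T,G} at offset +4, polar
{S,T,G} at +1, and hydrophobic {P,V,A} at -3 — and additionally
depletes the other classes' anchor groups at their positions,
mirroring the depletion patterns that two-sample logos show in real
substrate data.  The joint enrichment/depletion is what gives the
anchor positions a genuine pairwise dependence: a mixture of purely
single-position enrichments carries only weak chi-square signal at a
few hundred sequences and would not be decomposable.

The generator mimics positional residue composition only: no homology,
no domain structure, no realistic length distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from glycmotif.encoders import (
    PSIBLAST_COLUMNS,
    PSSMProfile,
    RESIDUE_ORDER,
    fallback_profile,
    write_pssm,
)
from glycmotif.seqdata import (
    AMINO_ACIDS,
    ProteinRecord,
    SequenceFragment,
    SiteRecord,
    WindowConfig,
    enumerate_negatives,
    extract_fragment,
    write_fasta,
    write_site_table,
)

#: Swiss-Prot-like residue frequencies (rounded, renormalized) as an
#: alternative to the default uniform background.
SWISSPROT_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif class.

    ``constraints`` lists enrichments (offset, residue set, probability);
    the first entry is the anchor.  ``depletions`` lists positions where
    a residue set is suppressed with the stated probability (the residue
    is overwritten by a uniform draw from the complement), the way real
    substrate classes deplete each other's signature groups.
    """

    name: str
    constraints: tuple[tuple[int, str, float], ...]
    depletions: tuple[tuple[int, str, float], ...] = ()
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError("motif needs at least one constraint")
        for offset, residues, p in self.constraints + self.depletions:
            if offset == 0:
                raise ValueError("constraints may not sit on the center offset")
            if not 0 < p <= 1:
                raise ValueError("constraint probability must be in (0, 1]")
            if not residues:
                raise ValueError("empty residue set")

    @property
    def anchor(self) -> tuple[int, str, float]:
        return self.constraints[0]


#: Full chemical groups used by the default depletions.
_POLAR = "STGNQC"
_HYDROPHOBIC = "AVLIPM"


def default_motifs(p_e: float = 0.9) -> tuple[MotifSpec, ...]:
    """The three default classes.

    Each class enriches its anchor (polar at +4, polar at +1,
    hydrophobic at -3) and depletes the other two anchors' full
    chemical groups at their positions with the same probability.
    """
    return (
        MotifSpec(
            "OG1",
            ((4, "STG", p_e),),
            ((1, _POLAR, p_e), (-3, _HYDROPHOBIC, p_e)),
        ),
        MotifSpec(
            "OG2",
            ((1, "STG", p_e),),
            ((4, _POLAR, p_e), (-3, _HYDROPHOBIC, p_e)),
        ),
        MotifSpec(
            "OG3",
            ((-3, "PVA", p_e),),
            ((4, _POLAR, p_e), (1, _POLAR, p_e)),
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the real training scale: 3 classes x 125 positives
    = 375 sites on ~100 proteins.  ``neg_pool_size`` caps the enumerated
    negative pool fed to K-means subsampling (the full ~70:1 enumerated
    ratio is available by setting it to 0 = no cap).
    """

    n_proteins: int = 100
    protein_length: int = 500
    background: dict[str, float] | None = None  # None -> uniform 1/20
    motifs: tuple[MotifSpec, ...] = field(default_factory=default_motifs)
    sites_per_class: int = 125
    neg_pool_size: int = 3000
    seed: int = 0
    window: WindowConfig = field(default_factory=WindowConfig)

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.protein_length < 2 * self.window.n + 1:
            raise ValueError("bad generator sizes")
        if self.background is not None:
            total = sum(self.background.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("background frequencies must sum to 1")

    def background_vector(self) -> np.ndarray:
        freqs = self.background or {aa: 1 / 20 for aa in AMINO_ACIDS}
        return np.array([freqs[aa] for aa in AMINO_ACIDS])


def generate_background(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[ProteinRecord]:
    """I.i.d. background proteins, seeded and reproducible."""
    rng = rng or np.random.default_rng(cfg.seed)
    probs = cfg.background_vector()
    alphabet = np.array(list(AMINO_ACIDS))
    records = []
    for k in range(cfg.n_proteins):
        seq = "".join(rng.choice(alphabet, size=cfg.protein_length, p=probs))
        records.append(ProteinRecord(f"SYN{k:04d}", seq))
    return records


def plant_positive_sites(
    proteins: list[ProteinRecord],
    motifs: tuple[MotifSpec, ...],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProteinRecord], list[SiteRecord], dict[tuple[str, int], str]]:
    """Plant ``sites_per_class`` sites per class; return edited proteins.

    Site centers are forced to S/T; planted windows keep a full margin
    from the termini and never overlap each other.  Each enrichment
    constraint fires with its stated probability and overwrites the
    residue at its offset with a uniform draw from the constraint's
    residue set; each depletion fires with its probability and
    overwrites with a uniform draw from the complement of its set.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.window.n
    seqs = {p.id: list(p.sequence) for p in proteins}
    ids = [p.id for p in proteins]
    occupied: dict[str, list[int]] = {pid: [] for pid in ids}
    sites: list[SiteRecord] = []
    truth: dict[tuple[str, int], str] = {}
    for spec in motifs:
        planted = 0
        attempts = 0
        limit = cfg.sites_per_class * 1000
        while planted < cfg.sites_per_class:
            attempts += 1
            if attempts > limit:
                raise ValueError("not enough room to plant positive sites")
            pid = ids[rng.integers(len(ids))]
            length = len(seqs[pid])
            pos = int(rng.integers(n + 1, length - n + 1))  # 1-based, full window
            if any(abs(pos - q) <= 2 * n for q in occupied[pid]):
                continue
            center = "S" if rng.random() < 0.5 else "T"
            seqs[pid][pos - 1] = center
            for offset, residues, p in spec.constraints:
                if rng.random() < p:
                    seqs[pid][pos - 1 + offset] = residues[int(rng.integers(len(residues)))]
            for offset, residues, p in spec.depletions:
                if rng.random() < p:
                    complement = [a for a in AMINO_ACIDS if a not in residues]
                    seqs[pid][pos - 1 + offset] = complement[int(rng.integers(len(complement)))]
            occupied[pid].append(pos)
            sites.append(SiteRecord(pid, pos, center, "positive", "planted"))
            truth[(pid, pos)] = spec.name
            planted += 1
    edited = [ProteinRecord(p.id, "".join(seqs[p.id])) for p in proteins]
    return edited, sites, truth


@dataclass
class SimulatedDataset:
    """Everything a benchmark run needs, already extracted."""

    proteins: dict[str, ProteinRecord]
    pos_sites: list[SiteRecord]
    neg_sites: list[SiteRecord]
    pos_fragments: list[SequenceFragment]
    neg_fragments: list[SequenceFragment]
    truth: dict[tuple[str, int], str]
    config: GeneratorConfig


def make_dataset(cfg: GeneratorConfig) -> SimulatedDataset:
    """Generate proteins, plant positives, enumerate the negative pool."""
    rng = np.random.default_rng(cfg.seed)
    proteins = generate_background(cfg, rng)
    proteins, pos_sites, truth = plant_positive_sites(proteins, cfg.motifs, cfg, rng)
    index = {p.id: p for p in proteins}
    neg_sites: list[SiteRecord] = []
    for prot in proteins:
        neg_sites.extend(enumerate_negatives(prot, pos_sites, cfg.window))
    if cfg.neg_pool_size and cfg.neg_pool_size < len(neg_sites):
        idx = sorted(
            rng.choice(len(neg_sites), size=cfg.neg_pool_size, replace=False).tolist()
        )
        neg_sites = [neg_sites[i] for i in idx]
    pos_fragments = [
        extract_fragment(index[s.protein_id], s.position, cfg.window, "positive")
        for s in pos_sites
    ]
    neg_fragments = [
        extract_fragment(index[s.protein_id], s.position, cfg.window, "negative")
        for s in neg_sites
    ]
    return SimulatedDataset(
        index, pos_sites, neg_sites, pos_fragments, neg_fragments, truth, cfg
    )


def random_fragments(
    n: int,
    cfg: GeneratorConfig = GeneratorConfig(),
    rng: np.random.Generator | None = None,
) -> list[SequenceFragment]:
    """Windows with i.i.d. background residues and an S/T center (null data)."""
    rng = rng or np.random.default_rng(cfg.seed)
    probs = cfg.background_vector()
    alphabet = np.array(list(AMINO_ACIDS))
    w = cfg.window.length
    out = []
    for k in range(n):
        chars = rng.choice(alphabet, size=w, p=probs)
        chars[cfg.window.n] = "S" if rng.random() < 0.5 else "T"
        out.append(SequenceFragment("".join(chars), cfg.window.n, f"NULL{k}", 1 + cfg.window.n, "positive"))
    return out


def _synthetic_profiles(
    data: SimulatedDataset, rng: np.random.Generator
) -> dict[str, PSSMProfile]:
    """Synthetic per-protein PSSMs (identity-biased + planted log-odds).

    A stand-in for PSI-BLAST output: every row scores its own residue
    +4 and others -1, and rows inside a planted window additionally get
    the positive-set log-odds for their offset, so evolutionary-style
    conservation of the planted motifs is visible to the PSSM encoder.
    """
    n = data.config.window.n
    logodds = fallback_profile(
        data.pos_fragments, cfg=data.config.window
    )  # (2n+1, 20) in RESIDUE_ORDER
    order_to_psi = [RESIDUE_ORDER.index(a) for a in PSIBLAST_COLUMNS]
    pos_by_protein: dict[str, list[int]] = {}
    for s in data.pos_sites:
        pos_by_protein.setdefault(s.protein_id, []).append(s.position)
    profiles = {}
    for pid, prot in data.proteins.items():
        L = len(prot.sequence)
        scores = np.full((L, 20), -1.0)
        for i, aa in enumerate(prot.sequence):
            if aa in PSIBLAST_COLUMNS:
                scores[i, PSIBLAST_COLUMNS.index(aa)] = 4.0
        for site_pos in pos_by_protein.get(pid, ()):
            for off in range(-n, n + 1):
                idx = site_pos - 1 + off
                if 0 <= idx < L:
                    scores[idx] += logodds[off + n][order_to_psi]
        profiles[pid] = PSSMProfile(pid, prot.sequence, np.round(scores, 2))
    return profiles


def make_fixture_bundle(cfg: GeneratorConfig, outdir) -> dict[str, Path]:
    """Write a self-consistent on-disk fixture dataset.

    Produces ``proteins.fasta``, ``sites.tsv`` (positives + negative
    pool), ``asa.tsv`` and one synthetic PSSM file per protein under
    ``pssm/``.  ASA values are drawn uniformly and damped by 30% inside
    positive windows, emulating the reduced solvent exposure observed
    around real modified sites.  Regeneration under the same seed is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = make_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.window.n

    fasta = outdir / "proteins.fasta"
    write_fasta(sorted(data.proteins.values(), key=lambda p: p.id), fasta)

    sites = outdir / "sites.tsv"
    write_site_table(data.pos_sites + data.neg_sites, sites)

    pos_by_protein: dict[str, set[int]] = {}
    for s in data.pos_sites:
        pos_by_protein.setdefault(s.protein_id, set()).add(s.position)
    asa = outdir / "asa.tsv"
    with open(asa, "w") as fh:
        fh.write("#protein_id\tposition\tasa_value\n")
        for pid in sorted(data.proteins):
            prot = data.proteins[pid]
            values = rng.uniform(20.0, 120.0, size=len(prot.sequence))
            for site_pos in pos_by_protein.get(pid, ()):
                lo = max(0, site_pos - 1 - n)
                hi = min(len(prot.sequence), site_pos + n)
                values[lo:hi] *= 0.7
            for i, v in enumerate(values, start=1):
                fh.write(f"{pid}\t{i}\t{v:.3f}\n")

    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    profiles = _synthetic_profiles(data, rng)
    for pid in sorted(profiles):
        write_pssm(profiles[pid], pssm_dir / f"{pid}.pssm")

    return {"fasta": fasta, "sites": sites, "asa": asa, "pssm_dir": pssm_dir}
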