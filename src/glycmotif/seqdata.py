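"""Sequence and site-annotation handling.

Reads protein FASTA files and site tables, extracts fixed-width sequence
windows centered on candidate serine/threonine residues, enumerates the
negative (unmodified S/T) sites of each protein, deduplicates site records
across sources, and counts proximity between two site sets (e.g. known
phosphosites near O-GlcNAc sites).

Conventions
-----------
* Positions are 1-based in all external files (UniProt convention);
  window offsets run -n..+n with the candidate site at offset 0;
  internal string indices are 0-based.
* Sequences are upper-cased on read; characters outside the 20-letter
  amino-acid alphabet are mapped to ``X`` (and logged) so that positions
  stay stable.
* Window termini beyond the protein ends are padded with ``-``; the pad
  character is treated as a dedicated "terminal" symbol downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Unknown-residue placeholder; never assigned to a chemical group.
UNKNOWN = "X"
#: Default terminal padding character for windows that overhang the sequence.
PAD = "-"

_VALID = set(AMINO_ACIDS) | {UNKNOWN}


class SiteValidationError(ValueError):
    """A site row failed validation against its protein sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SiteRecord:
    """A candidate or annotated S/T site, 1-based position."""

    protein_id: str
    position: int
    residue: str
    label: str  # "positive" | "negative"
    source: str = ""


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry: total length is ``2n + 1`` (11 for the default n=5)."""

    n: int = 5
    pad_char: str = PAD

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("half-window n must be >= 1")
        if len(self.pad_char) != 1 or self.pad_char in AMINO_ACIDS:
            raise ValueError("pad_char must be a single non-amino-acid character")

    @property
    def length(self) -> int:
        return 2 * self.n + 1


@dataclass(frozen=True)
class SequenceFragment:
    """A ``2n+1`` window centered on an S/T residue (offset 0 = the site)."""

    window: str
    center_index: int
    protein_id: str
    position: int
    label: str

    def at_offset(self, offset: int) -> str:
        """Residue at window offset (-n..+n relative to the site)."""
        return self.window[self.center_index + offset]


def clean_sequence(seq: str, protein_id: str = "?") -> str:
    """Upper-case *seq* and map characters outside the alphabet to ``X``."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    cleaned = []
    bad = set()
    for ch in seq:
        if ch in _VALID:
            cleaned.append(ch)
        else:
            bad.add(ch)
            cleaned.append(UNKNOWN)
    logger.warning("protein %s: mapped %s to X", protein_id, sorted(bad))
    return "".join(cleaned)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly multi-record) FASTA file into ProteinRecords.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, clean_sequence(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def protein_index(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.id: rec for rec in records}


def read_site_table(path) -> list[SiteRecord]:
    """Read a site TSV (protein_id, position, residue, label[, source]).

    Lines starting with ``#`` are comments.  Sites whose residue is not
    S or T are rejected here with an error: the method is defined only
    for serine/threonine.  Sequence-level validation (position range,
    residue identity) is done by :func:`validate_sites`.
    """
    sites: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            pid, pos_s, residue, label = parts[:4]
            source = parts[4] if len(parts) > 4 else ""
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            residue = residue.upper()
            if residue not in ("S", "T"):
                raise SiteValidationError(
                    f"{path}:{lineno}: residue {residue!r} is not S/T"
                )
            if label not in ("positive", "negative"):
                raise ValueError(f"{path}:{lineno}: bad label {label!r}")
            sites.append(SiteRecord(pid, pos, residue, label, source))
    return sites


def validate_sites(
    sites: Iterable[SiteRecord], proteins: Mapping[str, ProteinRecord]
) -> tuple[list[SiteRecord], list[str]]:
    """Check sites against sequences; return (valid, rejection reports)."""
    valid: list[SiteRecord] = []
    rejects: list[str] = []
    for s in sites:
        prot = proteins.get(s.protein_id)
        if prot is None:
            rejects.append(f"{s.protein_id}:{s.position}: unknown protein")
            continue
        if not 1 <= s.position <= len(prot.sequence):
            rejects.append(
                f"{s.protein_id}:{s.position}: position out of range "
                f"(length {len(prot.sequence)})"
            )
            continue
        actual = prot.sequence[s.position - 1]
        if actual != s.residue:
            rejects.append(
                f"{s.protein_id}:{s.position}: residue mismatch "
                f"(annotated {s.residue}, sequence has {actual})"
            )
            continue
        valid.append(s)
    if rejects:
        logger.warning("rejected %d site rows", len(rejects))
    return valid, rejects


def write_site_table(sites: Iterable[SiteRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tresidue\tlabel\tsource\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t{s.label}\t{s.source}\n")


def dedup_sites(
    sites: Sequence[SiteRecord], source_priority: Sequence[str] | None = None
) -> list[SiteRecord]:
    """Keep one record per (protein_id, position).

    With *source_priority* given, the record whose ``source`` ranks
    earliest in the list wins; otherwise the first-seen record wins.
    Output order follows first appearance of each key (stable), so the
    operation is idempotent.
    """

    def rank(rec: SiteRecord) -> int:
        if source_priority is None:
            return 0
        try:
            return source_priority.index(rec.source)
        except ValueError:
            return len(source_priority)

    best: dict[tuple[str, int], SiteRecord] = {}
    order: list[tuple[str, int]] = []
    for rec in sites:
        key = (rec.protein_id, rec.position)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rank(rec) < rank(best[key]):
            best[key] = rec
    return [best[k] for k in order]


def extract_fragment(
    protein: ProteinRecord,
    position: int,
    cfg: WindowConfig = WindowConfig(),
    label: str = "positive",
) -> SequenceFragment:
    """Extract the ``2n+1`` window centered at *position* (1-based).

    Flanks that fall outside the sequence are filled with the pad
    character.  The center residue must be S or T.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(f"{protein.id}: position {position} out of range")
    center = seq[position - 1]
    if center not in ("S", "T"):
        raise ValueError(
            f"{protein.id}:{position}: center residue {center!r} is not S/T"
        )
    i = position - 1
    n = cfg.n
    left = seq[max(0, i - n) : i]
    right = seq[i + 1 : i + 1 + n]
    window = (
        cfg.pad_char * (n - len(left)) + left + center + right + cfg.pad_char * (n - len(right))
    )
    assert len(window) == cfg.length
    return SequenceFragment(window, n, protein.id, position, label)


def extract_fragments(
    sites: Iterable[SiteRecord],
    proteins: Mapping[str, ProteinRecord],
    cfg: WindowConfig = WindowConfig(),
) -> list[SequenceFragment]:
    return [
        extract_fragment(proteins[s.protein_id], s.position, cfg, s.label) for s in sites
    ]


def enumerate_negatives(
    protein: ProteinRecord,
    positive_sites: Iterable[SiteRecord],
    cfg: WindowConfig = WindowConfig(),
) -> list[SiteRecord]:
    """All S/T positions of *protein* not listed positive, as negatives."""
    pos_positions = {
        s.position for s in positive_sites if s.protein_id == protein.id
    }
    negatives = []
    for i, ch in enumerate(protein.sequence, start=1):
        if ch in ("S", "T") and i not in pos_positions:
            negatives.append(SiteRecord(protein.id, i, ch, "negative", "enumerated"))
    return negatives


def count_proximal_pairs(
    siteset_a: Iterable[SiteRecord],
    siteset_b: Iterable[SiteRecord],
    max_dist: int = 5,
) -> int:
    """Number of sites in *b* within ``±max_dist`` residues of any site in *a*.

    Only same-protein proximity counts; a site of *b* that coincides
    exactly with a site of *a* (same protein and position) is not counted
    against that site (self-pair exclusion for overlapping sets).
    """
    by_protein: dict[str, list[int]] = {}
    for s in siteset_a:
        by_protein.setdefault(s.protein_id, []).append(s.position)
    count = 0
    for s in siteset_b:
        positions = by_protein.get(s.protein_id, ())
        if any(
            abs(s.position - p) <= max_dist and not (s.position == p)
            for p in positions
        ):
            count += 1
    return count


def write_fragments(fragments: Iterable[SequenceFragment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tposition\tlabel\twindow\n")
        for f in fragments:
            fh.write(f"{f.protein_id}\t{f.position}\t{f.label}\t{f.window}\n")


def read_fragments(path, cfg: WindowConfig = WindowConfig()) -> list[SequenceFragment]:
    fragments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, pos, label, window = line.split("\t")
            if len(window) != cfg.length:
                raise ValueError(f"{path}:{lineno}: window length != {cfg.length}")
            fragments.append(SequenceFragment(window, cfg.n, pid, int(pos), label))
    return fragments
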