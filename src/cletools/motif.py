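"""Tandem ARR motif scanning in protein sequences.

The arginine-rich region (ARR) that forms the c-di-GMP binding module of
Cle-family proteins consists of two copies of the degenerate core unit
``[YF] X G P [DE] [RK] R`` arranged in tandem, typically flanked by a
conserved Arg on the N-terminal side and an Asp on the C-terminal side. This
module finds such tandem placements in arbitrary protein sequences and
classifies candidate Cle-like proteins.

Matching is ambiguity-permissive: ``X`` in the pattern matches any residue,
and an ``X`` in the subject sequence satisfies any pattern class (maximizing
recall on partially determined sequences).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "ProteinRecord",
    "ArrMotifConfig",
    "MotifHit",
    "PartialHit",
    "read_fasta",
    "scan_arr",
    "classify_candidates",
    "CORE_UNIT",
]

#: The tandem-repeat core unit, one residue class per position.
CORE_UNIT = ("YF", "X", "G", "P", "DE", "RK", "R")

UNIT_LEN = len(CORE_UNIT)

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """A protein sequence (standard 20-letter alphabet plus X), uppercased."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.sequence.endswith("*"):
            self.sequence = self.sequence[:-1]
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise DataError(f"record {self.id!r}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class ArrMotifConfig:
    """Scan configuration.

    ``max_gap`` bounds the spacer between the two tandem units (default 8,
    keeping R + unit + gap + unit + D within the ~32-residue span of a
    natural ARR). ``flank_window`` is how far to look for the conserved
    N-terminal Arg / C-terminal Asp; ``require_flanks`` promotes the flanks
    from annotation to requirement.
    """

    max_gap: int = 8
    flank_window: int = 6
    require_flanks: bool = False

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ParameterError("max_gap must be >= 0")
        if self.flank_window < 1:
            raise ParameterError("flank_window must be >= 1")


@dataclass(frozen=True)
class MotifHit:
    """One tandem placement. Positions are 1-based inclusive."""

    protein_id: str
    unit1_start: int
    unit1_end: int
    unit2_start: int
    unit2_end: int
    gap: int
    flank_R_pos: int | None
    flank_D_pos: int | None
    matched: str

    @property
    def has_flanks(self) -> bool:
        return self.flank_R_pos is not None and self.flank_D_pos is not None


@dataclass(frozen=True)
class PartialHit:
    """A single core-unit match with no tandem partner."""

    protein_id: str
    start: int
    end: int
    matched: str


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Parse a protein FASTA file; sequences uppercased, terminal '*' stripped.

    Internal stop characters raise :class:`~cletools.errors.DataError` naming
    the record; an empty file raises :class:`~cletools.errors.FormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise DataError(f"record {rec.id!r}: internal stop character")
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


# Subject 'X' satisfies any class, so every class admits 'X'; the wildcard
# position admits everything. Lookahead makes matches overlapping.
_UNIT_RE = re.compile(
    "(?=" + "".join("." if c == "X" else f"[{c}X]" for c in CORE_UNIT) + ")"
)


def _unit_starts(seq: str) -> list[int]:
    """All (overlapping) 0-based start positions of the core unit."""
    return [m.start() for m in _UNIT_RE.finditer(seq)]


def _find_flanks(seq: str, u1_start0: int, u2_end0: int, window: int):
    """Nearest Arg before unit1 and Asp after unit2, within ``window`` residues."""
    r_pos = d_pos = None
    for i in range(u1_start0 - 1, max(u1_start0 - 1 - window, -1), -1):
        if seq[i] == "R":
            r_pos = i + 1  # 1-based
            break
    for i in range(u2_end0 + 1, min(u2_end0 + 1 + window, len(seq))):
        if seq[i] == "D":
            d_pos = i + 1
            break
    return r_pos, d_pos


def scan_arr(
    protein: ProteinRecord, cfg: ArrMotifConfig | None = None
) -> tuple[list[MotifHit], list[PartialHit]]:
    """Find tandem ARR placements (and leftover single-unit partial hits).

    Tandem placements are enumerated leftmost-first and greedily: the scan
    walks unit matches in order of start position, pairs each unconsumed unit
    with the nearest following unit whose gap is at most ``cfg.max_gap``,
    then continues after the second unit — so placements never share a unit.
    Unit matches not consumed by any tandem are reported as partial hits.
    """
    cfg = cfg or ArrMotifConfig()
    seq = protein.sequence
    starts = _unit_starts(seq)
    hits: list[MotifHit] = []
    partials: list[PartialHit] = []
    i = 0
    while i < len(starts):
        u1 = starts[i]
        u1_end0 = u1 + UNIT_LEN - 1
        partner = None
        for j in range(i + 1, len(starts)):
            gap = starts[j] - u1_end0 - 1
            if gap < 0:
                continue  # overlaps unit1
            if gap > cfg.max_gap:
                break
            partner = j
            break
        if partner is None:
            partials.append(
                PartialHit(protein.id, u1 + 1, u1_end0 + 1, seq[u1 : u1_end0 + 1])
            )
            i += 1
            continue
        u2 = starts[partner]
        u2_end0 = u2 + UNIT_LEN - 1
        r_pos, d_pos = _find_flanks(seq, u1, u2_end0, cfg.flank_window)
        hit = MotifHit(
            protein_id=protein.id,
            unit1_start=u1 + 1,
            unit1_end=u1_end0 + 1,
            unit2_start=u2 + 1,
            unit2_end=u2_end0 + 1,
            gap=u2 - u1_end0 - 1,
            flank_R_pos=r_pos,
            flank_D_pos=d_pos,
            matched=seq[u1 : u2_end0 + 1],
        )
        if cfg.require_flanks and not hit.has_flanks:
            partials.append(
                PartialHit(protein.id, u1 + 1, u1_end0 + 1, seq[u1 : u1_end0 + 1])
            )
            i += 1
            continue
        hits.append(hit)
        # consume every unit overlapping the placement, then continue after unit2
        i = partner + 1
        while i < len(starts) and starts[i] <= u2_end0:
            i += 1
    return hits, partials


def classify_candidates(
    proteins: list[ProteinRecord], cfg: ArrMotifConfig | None = None
) -> pd.DataFrame:
    """Per-protein tandem-hit census and candidate call, in input order.

    A protein is a candidate when it carries at least one tandem hit (with
    flanks, if ``cfg.require_flanks``).
    """
    if not proteins:
        raise ParameterError("need >= 1 protein")
    cfg = cfg or ArrMotifConfig()
    rows = []
    for prot in proteins:
        hits, _ = scan_arr(prot, cfg)
        rows.append(
            {
                "protein_id": prot.id,
                "n_tandem_hits": len(hits),
                "has_flanks": any(h.has_flanks for h in hits),
                "candidate": len(hits) > 0,
            }
        )
    return pd.DataFrame(rows)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Tandem hits as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "unit1_start": h.unit1_start,
                "unit1_end": h.unit1_end,
                "unit2_start": h.unit2_start,
                "unit2_end": h.unit2_end,
                "gap": h.gap,
                "flank_R_pos": h.flank_R_pos,
                "flank_D_pos": h.flank_D_pos,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=[
            "protein_id", "unit1_start", "unit1_end", "unit2_start",
            "unit2_end", "gap", "flank_R_pos", "flank_D_pos", "matched",
        ],
    )
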