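"""Degenerate short-linear-motif patterns and proteome scanning.

A motif pattern is an ordered list of residue classes over the 20 amino
acids, written with single letters, ``x`` for a wildcard position, and
square brackets for multi-residue classes (e.g. ``[YF]xFP``: Tyr or Phe,
anything, Phe, Pro). Scanning reports every window of a sequence, including
overlapping ones, whose residues satisfy the classes position by position.

Coordinates are 0-based half-open in memory; serialized tables use 1-based
inclusive coordinates, the convention biologists expect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlphabetError, InputError, PatternSyntaxError

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
#: Sequences may additionally contain X (unknown residue). An X satisfies
#: only wildcard positions: an unknown residue cannot confirm a constraint.
SEQUENCE_ALPHABET = AA_SET | {"X"}

WILDCARD = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class MotifPattern:
    """An ordered, fixed-width degenerate amino-acid pattern."""

    positions: tuple[frozenset[str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise PatternSyntaxError("pattern must have at least one position")
        for cls in self.positions:
            if not 1 <= len(cls) <= 20 or not cls <= AA_SET:
                raise PatternSyntaxError(f"invalid residue class {sorted(cls)!r}")

    @property
    def width(self) -> int:
        return len(self.positions)

    @property
    def n_constrained(self) -> int:
        """Number of positions whose class is narrower than the wildcard."""
        return sum(1 for cls in self.positions if len(cls) < 20)

    def matches_at(self, sequence: str, start: int) -> bool:
        """True if ``sequence[start:start+width]`` satisfies the pattern.

        An ``X`` in the sequence satisfies only wildcard positions.
        """
        for offset, cls in enumerate(self.positions):
            residue = sequence[start + offset]
            if residue == "X":
                if len(cls) < 20:
                    return False
            elif residue not in cls:
                return False
        return True

    def render(self) -> str:
        """Render back to pattern syntax (classes listed alphabetically)."""
        parts = []
        for cls in self.positions:
            if len(cls) == 20:
                parts.append("x")
            elif len(cls) == 1:
                parts.append(next(iter(cls)))
            else:
                parts.append("[" + "".join(sorted(cls)) + "]")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_pattern(pattern_text: str, label: Optional[str] = None) -> MotifPattern:
    """Parse pattern syntax into a :class:`MotifPattern`.

    Raises
    ------
    PatternSyntaxError
        On unbalanced brackets, an empty class, or a letter outside the 20
        amino acids; the message names the offending token.
    """
    positions: list[frozenset[str]] = []
    i = 0
    text = pattern_text
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced bracket at {text[i:]!r}")
            letters = text[i + 1 : j]
            if not letters:
                raise PatternSyntaxError("empty residue class '[]'")
            bad = sorted(set(letters) - AA_SET)
            if bad:
                raise PatternSyntaxError(f"non-amino-acid letter {bad[0]!r} in class {letters!r}")
            positions.append(frozenset(letters))
            i = j + 1
        elif ch == "]":
            raise PatternSyntaxError(f"unbalanced bracket at {text[i:]!r}")
        elif ch == "x":
            positions.append(WILDCARD)
            i += 1
        elif ch in AA_SET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise PatternSyntaxError(f"non-amino-acid letter {ch!r}")
    if not positions:
        raise PatternSyntaxError("empty pattern")
    return MotifPattern(tuple(positions), label=label if label is not None else pattern_text)


#: Built-in named patterns. ``consensus`` defaults to the Hx[RK]xx[ST] form
#: used in the proteome-wide co-conservation analyses; the stricter
#: HxRxx[ST] variant and the basic-position docking consensus are provided
#: under their own names.
PATTERNS: dict[str, MotifPattern] = {
    "docking": parse_pattern("[YF]xFP", label="docking"),
    "consensus": parse_pattern("Hx[RK]xx[ST]", label="consensus"),
    "consensus_hxr": parse_pattern("HxRxx[ST]", label="consensus_hxr"),
    "docking_basic": parse_pattern("[YF][KR]FP", label="docking_basic"),
}


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern in a protein (0-based half-open)."""

    protein_id: str
    start: int
    end: int
    matched_seq: str
    pattern_label: str


@dataclass(frozen=True)
class ProteomeRecord:
    """A protein sequence with a unique identifier."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"empty sequence for protein {self.protein_id!r}")
        validate_sequence(self.sequence, self.protein_id)

    @property
    def length(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, protein_id: str = "?") -> None:
    bad = sorted(set(sequence) - SEQUENCE_ALPHABET)
    if bad:
        raise AlphabetError(f"illegal character {bad[0]!r} in sequence of {protein_id!r}")


def scan_sequence(pattern: MotifPattern, sequence: str, protein_id: str = "") -> list[MotifMatch]:
    """All (possibly overlapping) matches of ``pattern`` in ``sequence``.

    Matches are sorted by start coordinate. Raises :class:`AlphabetError`
    on characters outside the 20 amino acids plus X.
    """
    validate_sequence(sequence, protein_id)
    w = pattern.width
    out = []
    for start in range(len(sequence) - w + 1):
        if pattern.matches_at(sequence, start):
            out.append(
                MotifMatch(protein_id, start, start + w, sequence[start : start + w], pattern.label)
            )
    return out


MASK_COLUMNS = ("protein_id", "start_1based", "end_1based")
MATCH_TABLE_COLUMNS = ("protein_id", "pattern_label", "start_1based", "end_1based", "matched_seq")


def scan_proteome(
    pattern: MotifPattern,
    proteome: Sequence[ProteomeRecord],
    mask: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> pd.DataFrame:
    """Scan every protein; returns the serialized match table.

    ``mask`` maps protein id to 0-based half-open intervals; when given,
    only matches lying fully inside a masked interval are kept (e.g. to
    restrict the scan to disordered segments). The returned DataFrame uses
    1-based inclusive coordinates (columns ``MATCH_TABLE_COLUMNS``) and has
    per-protein counts available via groupby; total = len(table).
    """
    seen: set[str] = set()
    rows = []
    for record in proteome:
        if record.protein_id in seen:
            raise InputError(f"duplicate protein id {record.protein_id!r}")
        seen.add(record.protein_id)
        matches = scan_sequence(pattern, record.sequence, record.protein_id)
        if mask is not None:
            intervals = mask.get(record.protein_id, ())
            matches = [
                m for m in matches if any(s <= m.start and m.end <= e for s, e in intervals)
            ]
        for m in matches:
            rows.append((m.protein_id, m.pattern_label, m.start + 1, m.end, m.matched_seq))
    return pd.DataFrame(rows, columns=MATCH_TABLE_COLUMNS)


def match_density(match_count: int, total_residues: int) -> float:
    """Matches per 1,000 amino acids."""
    if total_residues <= 0:
        raise InputError("total_residues must be positive")
    return 1000.0 * match_count / total_residues


def read_fasta_proteome(path: str | Path) -> list[ProteomeRecord]:
    """Read a proteome FASTA; id = first whitespace-delimited header token."""
    records = [ProteomeRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r.protein_id for r in records]
    dupes = {i for i, n in zip(ids, map(ids.count, ids)) if n > 1}
    if dupes:
        raise InputError(f"duplicate protein id {sorted(dupes)[0]!r} in {path}")
    return records


def read_mask(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a region-mask TSV (protein_id, start_1based, end_1based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(MASK_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"mask file {path} lacks columns {sorted(missing)}")
    mask: dict[str, list[tuple[int, int]]] = {}
    for pid, s1, e1 in df[list(MASK_COLUMNS)].itertuples(index=False):
        if s1 < 1 or e1 < s1:
            raise InputError(f"bad mask interval ({s1}, {e1}) for {pid!r}")
        mask.setdefault(str(pid), []).append((int(s1) - 1, int(e1)))
    return mask


def write_match_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
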