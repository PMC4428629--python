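"""Ortholog-group alignments, species trees and gap-aware coordinates.

An ortholog group is one reference protein plus species-tagged aligned
orthologs (FASTA with ``-`` gaps; headers ``species|protein_id``). The
coordinate maps translate between 0-based ungapped residue positions and
0-based alignment columns, and ``window_identity`` measures local
reference-vs-species percent identity, the background-conservation signal
the scoring model discounts against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InputError

GAP = "-"
#: Below this many comparable (both-ungapped) columns a window falls back
#: to whole-alignment identity, preventing degenerate 0/0 estimates.
MIN_COMPARABLE_COLUMNS = 5


@dataclass
class OrthologGroup:
    """A reference protein and its aligned orthologs, one row per species."""

    reference_id: str
    reference_species: str
    rows: dict[str, str]
    protein_ids: dict[str, str] = field(default_factory=dict)
    _col_of_pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _pos_of_col: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.reference_species not in self.rows:
            raise InputError(
                f"reference species {self.reference_species!r} missing from group "
                f"{self.reference_id!r}"
            )
        lengths = {len(row) for row in self.rows.values()}
        if len(lengths) != 1:
            for sp, row in self.rows.items():
                if len(row) != len(self.rows[self.reference_species]):
                    raise InputError(
                        f"row for species {sp!r} has length {len(row)}, expected "
                        f"{len(self.rows[self.reference_species])} (group {self.reference_id!r})"
                    )
        for sp, row in self.rows.items():
            if not row.replace(GAP, ""):
                raise InputError(f"row for species {sp!r} is all gaps (group {self.reference_id!r})")
        for sp, row in self.rows.items():
            aligned = np.frombuffer(row.encode(), dtype="S1") != GAP.encode()
            self._col_of_pos[sp] = np.flatnonzero(aligned)
            pos_of_col = np.full(len(row), -1, dtype=int)
            pos_of_col[aligned] = np.arange(aligned.sum())
            self._pos_of_col[sp] = pos_of_col

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, species: str) -> str:
        self._check_species(species)
        return self.rows[species].replace(GAP, "")

    def ungapped_to_column(self, species: str, position: int) -> int:
        """Alignment column holding the residue at ungapped ``position``."""
        self._check_species(species)
        cols = self._col_of_pos[species]
        if not 0 <= position < len(cols):
            raise InputError(
                f"position {position} out of range for {species!r} (ungapped length {len(cols)})"
            )
        return int(cols[position])

    def column_to_ungapped(self, species: str, column: int) -> Optional[int]:
        """Ungapped position at ``column``, or None if that row is gapped there."""
        self._check_species(species)
        if not 0 <= column < self.alignment_length:
            raise InputError(f"column {column} out of range")
        pos = int(self._pos_of_col[species][column])
        return None if pos < 0 else pos

    def window_identity(
        self,
        species: str,
        column_start: int,
        column_end: int,
        exclude_columns: Optional[frozenset[int] | set[int]] = None,
    ) -> float:
        """Fraction of identical reference/species residues in a column window.

        Columns where either row is gapped — and any ``exclude_columns``
        (e.g. the scored motif's own columns, so a motif is not discounted
        against itself) — are left out. With fewer than
        ``MIN_COMPARABLE_COLUMNS`` comparable columns the whole-alignment
        identity for the pair is returned instead.
        """
        self._check_species(species)
        if not (0 <= column_start <= column_end <= self.alignment_length):
            raise InputError(f"bad column range [{column_start}, {column_end})")
        ident, comparable = self._identity_counts(species, column_start, column_end, exclude_columns)
        if comparable < MIN_COMPARABLE_COLUMNS:
            ident, comparable = self._identity_counts(
                species, 0, self.alignment_length, exclude_columns
            )
            if comparable == 0:
                return 0.0
        return ident / comparable

    def _identity_counts(
        self,
        species: str,
        start: int,
        end: int,
        exclude_columns: Optional[frozenset[int] | set[int]] = None,
    ) -> tuple[int, int]:
        ref = self.rows[self.reference_species]
        other = self.rows[species]
        comparable = ident = 0
        for col in range(start, end):
            if exclude_columns and col in exclude_columns:
                continue
            a, b = ref[col], other[col]
            if a != GAP and b != GAP:
                comparable += 1
                if a == b:
                    ident += 1
        return ident, comparable

    def _check_species(self, species: str) -> None:
        if species not in self.rows:
            raise InputError(f"species {species!r} absent from group {self.reference_id!r}")


def read_ortholog_alignment(
    path: str | Path,
    reference_species: str,
    delimiter: str = "|",
) -> OrthologGroup:
    """Read one aligned FASTA into a validated :class:`OrthologGroup`.

    Headers carry ``species|protein_id`` (configurable delimiter). The
    reference species must appear exactly once.
    """
    rows: dict[str, str] = {}
    protein_ids: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if delimiter not in rec.id:
            raise InputError(f"header {rec.id!r} in {path} lacks delimiter {delimiter!r}")
        species, protein_id = rec.id.split(delimiter, 1)
        if species in rows:
            raise InputError(f"duplicate species {species!r} in {path}")
        rows[species] = str(rec.seq).upper()
        protein_ids[species] = protein_id
    if not rows:
        raise InputError(f"no records in {path}")
    if reference_species not in rows:
        raise InputError(f"reference species {reference_species!r} not found in {path}")
    return OrthologGroup(
        reference_id=protein_ids[reference_species],
        reference_species=reference_species,
        rows=rows,
        protein_ids=protein_ids,
    )


GROUP_INDEX_COLUMNS = ("reference_id", "path")


def read_group_index(path: str | Path) -> pd.DataFrame:
    """Read the group index TSV (reference_id -> alignment file path)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(GROUP_INDEX_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"group index {path} lacks columns {sorted(missing)}")
    return df


def iter_groups(
    index_path: str | Path, reference_species: str, delimiter: str = "|"
) -> Iterable[OrthologGroup]:
    base = Path(index_path).parent
    for _, row in read_group_index(index_path).iterrows():
        yield read_ortholog_alignment(base / row["path"], reference_species, delimiter)


def read_species_tree(newick_text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    The shape as written is taken as the rooted topology. Leaf labels must
    be unique; branch lengths, when present, must be non-negative.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"could not parse Newick tree: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})[0]
        raise InputError(f"duplicate leaf name {dup!r} in species tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError("negative branch length in species tree")
    return tree


def validate_group_species(group: OrthologGroup, tree: dendropy.Tree) -> None:
    """Every species in the group must be a leaf of the tree."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    extra = set(group.species) - leaves
    if extra:
        raise InputError(
            f"species {sorted(extra)} in group {group.reference_id!r} absent from species tree"
        )
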