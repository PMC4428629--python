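"""Co-occurrence and co-conservation enrichment statistics.

Builds 2x2 contingency tables over protein classes (e.g. proteins with a
conserved docking motif versus the rest) and outcomes (e.g. a consensus
match being among the most conserved, or being annotated as
phosphorylated), and tests them with Fisher's exact test. Density
comparisons are framed per 1,000 amino acids with residues as Bernoulli
trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .motifs import match_density

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = group membership, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise InputError("all-zero contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @classmethod
    def from_nested_counts(cls, k_in: int, n_in: int, k_total: int, n_total: int) -> "ContingencyTable":
        """Table from 'k_in of n_in inside the group' vs 'k_total of n_total overall'.

        The overall counts include the group, so the second row is the
        complement: (k_total - k_in) of (n_total - n_in).
        """
        if k_in > n_in or k_total > n_total or k_in > k_total or n_in > n_total:
            raise InputError("inconsistent nested counts")
        return cls(k_in, n_in - k_in, k_total - k_in, (n_total - n_in) - (k_total - k_in))


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float
    density_group1: Optional[float] = None  # per 1,000 residues, where applicable
    density_group2: Optional[float] = None


def _odds_ratio(t: ContingencyTable) -> float:
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:  # Haldane-Anscombe continuity correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact(table: ContingencyTable) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    One-sided = upper tail of the (a) cell (enrichment direction);
    two-sided = sum over tables whose point probability does not exceed
    the observed one (the standard minimum-likelihood rule).
    """
    arr = table.as_array()
    _, p_one = stats.fisher_exact(arr, alternative="greater")
    _, p_two = stats.fisher_exact(arr, alternative="two-sided")
    return EnrichmentResult(
        table=table,
        odds_ratio=_odds_ratio(table),
        p_one_sided=float(min(p_one, 1.0)),
        p_two_sided=float(min(p_two, 1.0)),
    )


def density_enrichment(
    matches1: int, residues1: int, matches2: int, residues2: int
) -> EnrichmentResult:
    """Compare motif densities between two protein classes.

    Residues are treated as Bernoulli trials (each position a potential
    motif start): the table is (matches, residues - matches) per class.
    Densities are reported per 1,000 amino acids. Callers wanting the
    window-count correction should pass ``sum(L_i - w + 1)`` as the residue
    totals.
    """
    if matches1 > residues1 or matches2 > residues2:
        raise InputError("match count exceeds residue total")
    table = ContingencyTable(matches1, residues1 - matches1, matches2, residues2 - matches2)
    base = fisher_exact(table)
    return EnrichmentResult(
        table=table,
        odds_ratio=base.odds_ratio,
        p_one_sided=base.p_one_sided,
        p_two_sided=base.p_two_sided,
        density_group1=match_density(matches1, residues1),
        density_group2=match_density(matches2, residues2),
    )


@dataclass(frozen=True)
class TopK:
    """Flag the k highest best-scores (boundary ties broken by protein id)."""

    k: int


@dataclass(frozen=True)
class Threshold:
    """Flag best-scores >= t."""

    t: float


def classify_conserved(
    scores: Mapping[str, float], rule: TopK | Threshold
) -> set[str]:
    """Protein ids flagged as conserved under a top-k or threshold rule."""
    if isinstance(rule, Threshold):
        return {pid for pid, s in scores.items() if s >= rule.t}
    if not isinstance(rule, TopK):
        raise InputError(f"unknown classification rule {rule!r}")
    if not 0 < rule.k <= len(scores):
        raise InputError(f"top-k rule needs 0 < k <= {len(scores)}, got {rule.k}")
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    boundary = ranked[rule.k - 1][1]
    if rule.k < len(ranked) and ranked[rule.k][1] == boundary:
        tied = [pid for pid, s in ranked if s == boundary]
        logger.warning(
            "top-%d boundary tie at score %g among %d proteins; keeping the "
            "lexicographically smallest ids",
            rule.k,
            boundary,
            len(tied),
        )
    return {pid for pid, _ in ranked[: rule.k]}


def annotation_overlap(
    consensus_matches: pd.DataFrame,
    annotations: pd.DataFrame,
    conserved_proteins: set[str],
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> EnrichmentResult:
    """Phospho-annotation enrichment of consensus matches by protein class.

    A consensus match is annotated when its [S/T] acceptor (the last
    pattern position; 1-based coordinate = end_1based) appears in the
    annotation table (columns ``protein_id``, ``position_1based``). The 2x2
    crosses (annotated, not) with (match in a conserved-docking protein,
    not). Annotation rows whose position exceeds the protein length are
    skipped with a warning.
    """
    required = {"protein_id", "position_1based"}
    if not required <= set(annotations.columns):
        raise InputError(f"annotation table lacks columns {sorted(required - set(annotations.columns))}")
    annotated_sites = set()
    for pid, pos in annotations[["protein_id", "position_1based"]].itertuples(index=False):
        pid = str(pid)
        pos = int(pos)
        if protein_lengths is not None and pid in protein_lengths and pos > protein_lengths[pid]:
            logger.warning("annotation at %s:%d beyond protein length; row skipped", pid, pos)
            continue
        annotated_sites.add((pid, pos))
    a = b = c = d = 0
    for pid, end1 in consensus_matches[["protein_id", "end_1based"]].itertuples(index=False):
        annotated = (str(pid), int(end1)) in annotated_sites
        in_group = str(pid) in conserved_proteins
        if in_group and annotated:
            a += 1
        elif in_group:
            b += 1
        elif annotated:
            c += 1
        else:
            d += 1
    return fisher_exact(ContingencyTable(a, b, c, d))


SCATTER_COLUMNS = (
    "protein_id",
    "docking_score",
    "consensus_score",
    "docking_rank",
    "consensus_rank",
    "joint_rank",
    "both_conserved",
)


def coconservation_scatter(
    docking_scores: Mapping[str, float],
    consensus_scores: Mapping[str, float],
    docking_rule: TopK | Threshold,
    consensus_rule: TopK | Threshold,
) -> pd.DataFrame:
    """Per-protein dual-score table (x = docking, y = consensus).

    Proteins scored on both axes get a joint rank (the better of their two
    per-axis ranks, 1 = most conserved) and a flag when conserved under
    both rules. Proteins scored on only one axis appear with NaN on the
    other and can never be flagged.
    """
    dock_set = classify_conserved(docking_scores, docking_rule) if docking_scores else set()
    cons_set = classify_conserved(consensus_scores, consensus_rule) if consensus_scores else set()

    def ranks(scores: Mapping[str, float]) -> dict[str, int]:
        ordered = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
        return {pid: i + 1 for i, (pid, _) in enumerate(ordered)}

    dock_rank = ranks(docking_scores)
    cons_rank = ranks(consensus_scores)
    rows = []
    for pid in sorted(set(docking_scores) | set(consensus_scores)):
        dr = dock_rank.get(pid)
        cr = cons_rank.get(pid)
        joint = min(r for r in (dr, cr) if r is not None) if (dr or cr) else None
        rows.append(
            (
                pid,
                docking_scores.get(pid, float("nan")),
                consensus_scores.get(pid, float("nan")),
                dr if dr is not None else -1,
                cr if cr is not None else -1,
                joint if joint is not None else -1,
                pid in dock_set and pid in cons_set,
            )
        )
    return pd.DataFrame(rows, columns=SCATTER_COLUMNS)
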