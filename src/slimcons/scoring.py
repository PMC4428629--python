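"""Conservation scoring of motif instances against a neutral-retention null.

The model follows the ConDens-style logic: for a motif match in the
reference protein, each ortholog species either retains the match (its
residues at the reference-aligned columns still satisfy the pattern) or
not. Under neutrality, retention is unsurprising wherever the local
background conservation is high, so each species' retention probability is
modelled as ``r_s = I_s ** k`` — the local reference/species identity
``I_s`` over a window of ``W`` alignment columns, raised to the number of
constrained pattern positions ``k`` — floored at the de-novo window match
probability ``q_s`` implied by the species' residue composition. The
species p-value is ``p_s = r_s`` if the match is retained and 1 otherwise,
and the per-match score is ``S = sum(-ln p_s)``: a motif sitting in a
highly conserved region contributes ~0 no matter how many species keep it,
while retention across diverged backgrounds accumulates evidence.

Because ``p_s`` is two-valued, the classic chi-square tail of Fisher's
combination is far too conservative as a significance measure for ``S``;
the primary ``combined_p`` is therefore the exact tail probability of ``S``
under the fitted retention null, with the mid-p convention for
discreteness. When the species tree is supplied (:class:`PhyloRetentionNull`)
the null draws the species' retention indicators jointly from a two-state
(in-class / out-of-class) Markov chain along the reference-rooted tree, so
that species sharing most of their path to the reference are correlated
under the null exactly as they are in neutral data; without a tree the
retentions are treated as independent Bernoulli(``r_s``), which is
anti-conservative on deeply structured phylogenies. The chi-square Fisher
value is also computed (``combined_p_chisq``) and the
:func:`combine_fisher` primitive is exposed for even-degrees-of-freedom
combination of ordinary p-values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .motifs import AMINO_ACIDS, MotifMatch, MotifPattern, scan_sequence
from .orthologs import GAP, OrthologGroup

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Default local-identity window width, in alignment columns.
DEFAULT_WINDOW = 15
#: Default composition pseudocount.
DEFAULT_PSEUDOCOUNT = 0.5

_PFLOOR = 1e-300


def background_composition(
    sequences: str | Iterable[str], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """Pseudocount-smoothed residue frequencies over the 20 amino acids.

    ``f(a) = (count_a + pseudocount) / (N + 20 * pseudocount)`` where ``N``
    counts standard residues only (gaps and X are ignored).
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(20)
    for seq in sequences:
        for ch in seq:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    n = counts.sum()
    if n == 0:
        raise InputError("no standard residues: cannot estimate composition")
    return (counts + pseudocount) / (n + 20 * pseudocount)


def motif_match_prob(pattern: MotifPattern, freqs: np.ndarray) -> float:
    """Probability that one random window matches: product of class masses."""
    q = 1.0
    for cls in pattern.positions:
        q *= float(sum(freqs[AA_INDEX[a]] for a in cls))
    return q


def expected_matches(width: int, ungapped_length: int, q: float) -> float:
    """Expected match count in a sequence: (L - w + 1) * q, 0 if L < w."""
    n_windows = ungapped_length - width + 1
    return max(n_windows, 0) * q


def poisson_upper_tail(m: int, lam: float) -> float:
    """P(X >= m) for X ~ Poisson(lam), clamped into (0, 1]."""
    if m < 0:
        raise InputError("m must be a non-negative integer")
    if m == 0:
        return 1.0
    return float(min(1.0, max(stats.poisson.sf(m - 1, lam), _PFLOOR)))


def combine_fisher(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2 sum(ln p); chi-square tail with 2n dof.

    Uses the closed form for even degrees of freedom,
    ``exp(-X/2) * sum_{j<n} (X/2)^j / j!``, evaluated in log space.
    """
    ps = list(p_values)
    if not ps:
        raise InputError("no p-values to combine")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise InputError(f"p-value {p} outside (0, 1]")
    x = -2.0 * sum(math.log(p) for p in ps)
    n = len(ps)
    if x <= 0.0:
        return 0.0, 1.0
    half = x / 2.0
    log_half = math.log(half)
    tail = sum(math.exp(-half + j * log_half - math.lgamma(j + 1)) for j in range(n))
    return x, float(min(1.0, max(tail, _PFLOOR)))


@dataclass
class NullModel:
    """Per-species composition-based null for one pattern.

    ``freqs[s]`` are the smoothed residue frequencies of species ``s``'s
    ungapped sequence, ``q[s]`` the per-window match probability of the
    pattern under them, and ``window`` the local-identity width ``W``.
    """

    freqs: dict[str, np.ndarray]
    q: dict[str, float]
    window: int = DEFAULT_WINDOW
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    global_identity: Optional[dict[str, float]] = None

    @classmethod
    def from_group(
        cls,
        group: OrthologGroup,
        pattern: MotifPattern,
        window: int = DEFAULT_WINDOW,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "NullModel":
        freqs = {
            sp: background_composition(group.ungapped(sp), pseudocount) for sp in group.species
        }
        q = {sp: motif_match_prob(pattern, f) for sp, f in freqs.items()}
        for sp, qs in q.items():
            if not 0.0 < qs < 1.0:
                raise InputError(f"degenerate window match probability {qs} for {sp!r}")
        global_identity = {
            sp: group.window_identity(sp, 0, group.alignment_length)
            for sp in group.species
            if sp != group.reference_species
        }
        return cls(
            freqs=freqs,
            q=q,
            window=window,
            pseudocount=pseudocount,
            global_identity=global_identity,
        )


@dataclass(frozen=True)
class SpeciesEvidence:
    """Retention evidence for one non-reference species at one match."""

    species: str
    retained: bool
    local_identity: float
    null_retention: float  # r_s = max(I_s, q_s^(1/k))^k, floored at q_s
    p_value: float  # r_s if retained else 1


def match_retention_evidence(
    match: MotifMatch,
    pattern: MotifPattern,
    group: OrthologGroup,
    null_model: NullModel,
) -> list[SpeciesEvidence]:
    """Per-species retention evidence for one reference match.

    Retention requires the species' residues at the reference-aligned
    columns to satisfy the pattern position by position; any gap in those
    columns breaks the match. The local identity window (``W`` columns) is
    centered on the match.
    """
    ref = group.reference_species
    cols = [group.ungapped_to_column(ref, pos) for pos in range(match.start, match.end)]
    w = null_model.window
    span = len(cols)
    center = (cols[0] + cols[-1] + 1) // 2
    width = max(w, span + 2)  # at least one background column each side
    col_start = max(0, center - width // 2)
    col_end = min(group.alignment_length, col_start + width)
    col_start = max(0, col_end - width)
    match_cols = frozenset(cols)

    k = pattern.n_constrained
    out = []
    for species in group.species:
        if species == ref:
            continue
        row = group.rows[species]
        retained = True
        for col, cls in zip(cols, pattern.positions):
            residue = row[col]
            if residue == GAP:
                retained = False
                break
            if residue == "X":
                if len(cls) < 20:
                    retained = False
                    break
            elif residue not in cls:
                retained = False
                break
        identity = group.window_identity(species, col_start, col_end, exclude_columns=match_cols)
        q_s = null_model.q[species]
        if k == 0:
            r_s = 1.0
        else:
            r_s = max(identity, q_s ** (1.0 / k)) ** k
            r_s = min(max(r_s, q_s), 1.0)
        p_s = r_s if retained else 1.0
        out.append(SpeciesEvidence(species, retained, identity, r_s, p_s))
    return out


def _retention_null_atoms(r_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of S = sum(-ln r_s * B_s), B_s ~ Bernoulli(r_s)."""
    xs = np.array([0.0])
    ps = np.array([1.0])
    for r in r_values:
        if r >= 1.0:
            continue
        v = -math.log(r)
        xs = np.concatenate([xs, xs + v])
        ps = np.concatenate([ps * (1.0 - r), ps * r])
        if len(xs) > 65536:  # merge numerically identical atoms
            keys = np.round(xs, 9)
            uniq, inverse = np.unique(keys, return_inverse=True)
            ps = np.bincount(inverse, weights=ps)
            xs = uniq
    return xs, ps


def retention_null_tail(evidence: Sequence[SpeciesEvidence], mid_p: bool = True) -> float:
    """Exact tail probability of the observed score under the fitted null.

    The null draws each species' retention independently with probability
    ``r_s``; the statistic is ``S = sum(-ln r_s)`` over retained species.
    With ``mid_p`` (default) half the probability of the observed atom is
    counted, which makes the p-value approximately uniform under the null
    despite its discreteness; without it the tail is conservative.
    """
    s_obs = sum(-math.log(ev.null_retention) for ev in evidence if ev.retained)
    xs, ps = _retention_null_atoms([ev.null_retention for ev in evidence])
    tol = 1e-9 * max(1.0, s_obs)
    ge = float(ps[xs >= s_obs - tol].sum())
    if mid_p:
        eq = float(ps[np.abs(xs - s_obs) <= tol].sum())
        ge -= 0.5 * eq
    return float(min(1.0, max(ge, _PFLOOR)))


class PhyloRetentionNull:
    """Joint neutral-retention null on the reference-rooted species tree.

    Per constrained pattern column, class membership under neutral drift is
    a two-state (in-class / out-of-class) Markov chain along the tree:
    with substitution probability ``1 - exp(-u)`` on an edge of length
    ``u``, the replacement lands in the class with its composition mass.
    Conditioning on the reference being in class, the joint law of the
    species' retention indicators is computed exactly by peeling, so
    species that share most of their path to the reference are correlated
    under the null just as they are in neutral data — the correction the
    independent-Bernoulli null lacks on structured phylogenies.

    A single family-specific rate scale is fitted by regressing the path
    costs implied by the observed local identities on the tree's path
    lengths, which lets one tree serve families evolving at different
    rates. Trees without branch lengths get unit lengths; the fitted scale
    absorbs the units.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        reference_species: str,
        max_species: int = 14,
        condition_on_root: bool = True,
    ) -> None:
        self.reference_species = reference_species
        self.max_species = max_species
        self.condition_on_root = condition_on_root
        # Undirected adjacency with edge lengths, then re-rooted at the
        # reference leaf by a DFS.
        index: dict[int, int] = {}
        labels: dict[int, Optional[str]] = {}
        adjacency: dict[int, list[tuple[int, float]]] = {}

        def idx(node: dendropy.Node) -> int:
            key = id(node)
            if key not in index:
                index[key] = len(index)
                labels[index[key]] = node.taxon.label if node.taxon else None
                adjacency[index[key]] = []
            return index[key]

        ref_idx = None
        self.ancestor = idx(tree.seed_node)
        for node in tree.preorder_node_iter():
            i = idx(node)
            if node.is_leaf() and node.taxon.label == reference_species:
                ref_idx = i
            for child in node.child_nodes():
                j = idx(child)
                length = child.edge.length if child.edge.length is not None else 1.0
                adjacency[i].append((j, float(length)))
                adjacency[j].append((i, float(length)))
        if ref_idx is None:
            raise InputError(f"reference species {reference_species!r} is not a leaf of the tree")
        self.root = ref_idx
        self.children: dict[int, list[tuple[int, float]]] = {}
        self.postorder: list[int] = []
        self.leaf_label: dict[int, str] = {
            i: lab for i, lab in labels.items() if lab is not None
        }
        self.path_cost: dict[str, float] = {}
        stack = [(ref_idx, -1, 0.0)]
        order = []
        while stack:
            node, parent, dist = stack.pop()
            order.append(node)
            if node in self.leaf_label and node != ref_idx:
                self.path_cost[self.leaf_label[node]] = dist
            self.children[node] = []
            for nbr, length in adjacency[node]:
                if nbr != parent:
                    self.children[node].append((nbr, length))
                    stack.append((nbr, node, dist + length))
        self.postorder = list(reversed(order))  # children before parents

    def _peel(
        self,
        alpha: float,
        pi: float,
        bit_of_leaf: dict[str, int],
        member: list[np.ndarray],
        size: int,
    ) -> np.ndarray:
        """P(all species in subset T in-class [and ancestor in-class] | ref in-class)."""
        l_in: dict[int, np.ndarray] = {}
        l_out: dict[int, np.ndarray] = {}
        for node in self.postorder:
            label = self.leaf_label.get(node)
            if label is not None and label in bit_of_leaf and node != self.root:
                mem = member[bit_of_leaf[label]]
                lin = np.ones(size)
                lout = 1.0 - mem.astype(float)
            else:
                lin = np.ones(size)
                lout = np.ones(size)
            if self.condition_on_root and node == self.ancestor and node != self.root:
                lout = np.zeros(size)  # ancestral presence: root forced in-class
            for child, length in self.children[node]:
                u = alpha * length
                decay = math.exp(-u)
                m_ii = decay + (1.0 - decay) * pi
                m_io = (1.0 - decay) * (1.0 - pi)
                m_oi = (1.0 - decay) * pi
                m_oo = decay + (1.0 - decay) * (1.0 - pi)
                lin = lin * (m_ii * l_in[child] + m_io * l_out[child])
                lout = lout * (m_oi * l_in[child] + m_oo * l_out[child])
            l_in[node] = lin
            l_out[node] = lout
        return l_in[self.root]

    def combined_p(
        self,
        evidence: Sequence["SpeciesEvidence"],
        pattern: MotifPattern,
        null_model: "NullModel",
        mid_p: bool = True,
    ) -> Optional[float]:
        """Mid-p tail of the observed score under the joint null.

        Returns None (caller falls back to the independent null) when a
        species is missing from the tree or there are too many species for
        exact subset enumeration.
        """
        ev = list(evidence)
        n = len(ev)
        if n == 0 or pattern.n_constrained == 0:
            return 1.0
        if n > self.max_species:
            return None
        if any(e.species not in self.path_cost for e in ev):
            return None
        fref = null_model.freqs[self.reference_species]
        # Family-specific rate scale from whole-alignment identities (the
        # local identities drive the discount weights, but are far too
        # noisy over a W-column window to set the chain's divergence).
        ts = []
        bs = []
        for e in ev:
            if null_model.global_identity and e.species in null_model.global_identity:
                identity = null_model.global_identity[e.species]
            else:
                identity = e.local_identity
            chance = float(np.dot(fref, null_model.freqs[e.species]))
            frac = (identity - chance) / (1.0 - chance)
            t = 0.0 if frac >= 1.0 else -math.log(max(frac, 1e-9))
            ts.append(min(t, 20.0))
            bs.append(self.path_cost[e.species])
        denom = sum(b * b for b in bs)
        alpha = (sum(t * b for t, b in zip(ts, bs)) / denom) if denom > 0 else 1.0
        alpha = min(max(alpha, 1e-6), 1e3)

        size = 1 << n
        member = [((np.arange(size) >> i) & 1).astype(bool) for i in range(n)]
        bit_of_leaf = {e.species: i for i, e in enumerate(ev)}
        masses = [
            float(sum(fref[AA_INDEX[a]] for a in cls))
            for cls in pattern.positions
            if len(cls) < 20
        ]
        p_superset = np.ones(size)
        for mass, count in Counter(round(m, 12) for m in masses).items():
            q = self._peel(alpha, float(mass), bit_of_leaf, member, size)
            # Normalize by the empty-subset value: with the ancestral-presence
            # condition the peel returns joint (not conditional) probabilities.
            if q[0] > 0:
                q = q / q[0]
            p_superset = p_superset * np.clip(q, 0.0, 1.0) ** count
        # Moebius inversion: P(retention set == R) from P(retention ⊇ T).
        probs = p_superset.copy()
        for i in range(n):
            without = np.flatnonzero(~member[i])
            probs[without] -= probs[without + (1 << i)]
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if total <= 0:
            return None
        probs /= total

        v = np.array(
            [-math.log(e.null_retention) if e.null_retention < 1.0 else 0.0 for e in ev]
        )
        svals = np.zeros(size)
        for i in range(n):
            svals[member[i]] += v[i]
        s_obs = float(sum(v[i] for i, e in enumerate(ev) if e.retained))
        tol = 1e-9 * max(1.0, s_obs)
        tail = float(probs[svals >= s_obs - tol].sum())
        if mid_p:
            tail -= 0.5 * float(probs[np.abs(svals - s_obs) <= tol].sum())
        return float(min(1.0, max(tail, _PFLOOR)))


@dataclass
class MotifConservationScore:
    """Combined conservation evidence for one motif match."""

    match: MotifMatch
    evidence: list[SpeciesEvidence]
    score: float  # S = sum(-ln p_s)
    combined_p: float  # calibrated retention-null tail (mid-p)
    combined_p_chisq: float  # Fisher chi-square combination of the p_s
    n_species_retained: int


def score_match(
    match: MotifMatch,
    pattern: MotifPattern,
    group: OrthologGroup,
    null_model: NullModel,
    phylo_null: Optional[PhyloRetentionNull] = None,
) -> MotifConservationScore:
    evidence = match_retention_evidence(match, pattern, group, null_model)
    score = sum(-math.log(ev.p_value) for ev in evidence)
    if evidence:
        _, p_chisq = combine_fisher([ev.p_value for ev in evidence])
        combined_p = None
        if phylo_null is not None:
            combined_p = phylo_null.combined_p(evidence, pattern, null_model)
        if combined_p is None:
            combined_p = retention_null_tail(evidence)
    else:
        p_chisq = 1.0
        combined_p = 1.0
    return MotifConservationScore(
        match=match,
        evidence=evidence,
        score=score,
        combined_p=combined_p,
        combined_p_chisq=p_chisq,
        n_species_retained=sum(ev.retained for ev in evidence),
    )


@dataclass
class ProteinScore:
    """Best per-match conservation score for one protein and pattern."""

    protein_id: str
    pattern_label: str
    best_score: float
    best_match: MotifMatch
    best: MotifConservationScore
    density_p: Optional[float] = None


def protein_motif_score(
    group: OrthologGroup,
    pattern: MotifPattern,
    null_model: Optional[NullModel] = None,
    with_density: bool = False,
    phylo_null: Optional[PhyloRetentionNull] = None,
) -> Optional[ProteinScore]:
    """Score every match in the group's reference protein; keep the best.

    Ties on the score are broken toward the smallest start coordinate.
    Returns None when the reference has no match (the protein is then
    omitted from score tables).
    """
    if null_model is None:
        null_model = NullModel.from_group(group, pattern)
    ref_seq = group.ungapped(group.reference_species)
    matches = scan_sequence(pattern, ref_seq, group.reference_id)
    if not matches:
        return None
    scored = [score_match(m, pattern, group, null_model, phylo_null) for m in matches]
    best = max(scored, key=lambda sc: (sc.score, -sc.match.start))
    result = ProteinScore(
        protein_id=group.reference_id,
        pattern_label=pattern.label,
        best_score=best.score,
        best_match=best.match,
        best=best,
    )
    if with_density:
        _, result.density_p = density_pvalue(group, pattern, null_model)
    return result


def density_pvalue(
    group: OrthologGroup,
    pattern: MotifPattern,
    null_model: Optional[NullModel] = None,
) -> tuple[dict[str, float], float]:
    """Whole-protein match-density comparison against the reference.

    For each non-reference species the observed match count ``T_s`` in its
    ungapped sequence is compared with ``mu_s = lambda_s + sum_j r_s(j)``
    (de-novo expectation plus neutral retention of each reference match)
    via the Poisson upper tail; species p-values are combined with
    Fisher's method. This is alignment-free on the species side: matches
    that moved still count. Returns (per-species p, combined p).
    """
    if null_model is None:
        null_model = NullModel.from_group(group, pattern)
    ref = group.reference_species
    ref_matches = scan_sequence(pattern, group.ungapped(ref), group.reference_id)
    per_match_evidence = [
        match_retention_evidence(m, pattern, group, null_model) for m in ref_matches
    ]
    per_species: dict[str, float] = {}
    for species in group.species:
        if species == ref:
            continue
        seq = group.ungapped(species)
        t_s = len(scan_sequence(pattern, seq, species))
        lam = expected_matches(pattern.width, len(seq), null_model.q[species])
        mu = lam + sum(
            ev.null_retention
            for evidence in per_match_evidence
            for ev in evidence
            if ev.species == species
        )
        per_species[species] = poisson_upper_tail(t_s, mu)
    if not per_species:
        return per_species, 1.0
    _, combined = combine_fisher(list(per_species.values()))
    return per_species, combined


SCORE_TABLE_COLUMNS = (
    "protein_id",
    "pattern_label",
    "start_1based",
    "end_1based",
    "matched_seq",
    "n_species_retained",
    "score",
    "combined_p",
    "combined_p_chisq",
    "density_p",
)


def score_table(
    groups: Iterable[OrthologGroup],
    pattern: MotifPattern,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    with_density: bool = False,
    tree: Optional[dendropy.Tree] = None,
) -> pd.DataFrame:
    """Per-protein best-score table over many ortholog groups (1-based coords).

    With ``tree`` supplied, combined p-values use the joint
    :class:`PhyloRetentionNull`; otherwise the independent retention null.
    """
    rows = []
    phylo_nulls: dict[str, PhyloRetentionNull] = {}
    for group in groups:
        phylo_null = None
        if tree is not None:
            ref = group.reference_species
            if ref not in phylo_nulls:
                phylo_nulls[ref] = PhyloRetentionNull(tree, ref)
            phylo_null = phylo_nulls[ref]
        null_model = NullModel.from_group(group, pattern, window, pseudocount)
        ps = protein_motif_score(
            group, pattern, null_model, with_density=with_density, phylo_null=phylo_null
        )
        if ps is None:
            continue
        m = ps.best_match
        rows.append(
            (
                ps.protein_id,
                ps.pattern_label,
                m.start + 1,
                m.end,
                m.matched_seq,
                ps.best.n_species_retained,
                ps.best_score,
                ps.best.combined_p,
                ps.best.combined_p_chisq,
                ps.density_p if ps.density_p is not None else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS)
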