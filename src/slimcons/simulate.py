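"""Synthetic ortholog families with planted, selection-maintained motifs.

The generator emulates the statistical structure the analysis assumes:
families of budding-yeast-like orthologs diverging neutrally along a
species tree (per site per branch, a substitution occurs with probability
``1 - exp(-b)`` and the replacement residue is resampled from the
background composition), with motif instances planted at a chosen gain
node and maintained by selection of tunable strength ``sigma``: a
replacement that would leave the pattern's residue class is rejected with
probability ``sigma`` (1 = class-preserving, 0 = fully neutral). Because
there are no indels by default, rows align trivially and every scoring
decision can be checked against closed-form neutral expectations. An
optional deletion mode introduces geometric-length gap runs to exercise
gap handling downstream.

Everything is driven by one integer seed and is byte-identical across
runs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError
from .motifs import AMINO_ACIDS, MotifMatch, MotifPattern, PATTERNS, ProteomeRecord
from .orthologs import OrthologGroup, read_species_tree
from .scoring import NullModel, PhyloRetentionNull, score_match

AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

#: Default species tree: a six-taxon budding-yeast-like topology with
#: amino-acid branch lengths (substitutions per site) typical of post-WGD
#: and related yeasts; Scer is the reference.
DEFAULT_TREE = (
    "(((Scer:0.10,Sbay:0.12):0.08,Cgla:0.26):0.10,"
    "((Klac:0.22,Agos:0.24):0.09,Kwal:0.27):0.13);"
)
DEFAULT_REFERENCE = "Scer"

#: Residue frequencies skewed toward disorder-promoting residues
#: (P/E/S/K/Q/G enriched; W/C/F/Y/I depleted), for composition-sensitivity
#: checks. The default background is uniform.
DISORDER_COMPOSITION = np.array(
    #  A     C     D     E     F     G     H     I     K     L
    [0.070, 0.005, 0.055, 0.090, 0.020, 0.075, 0.020, 0.025, 0.080, 0.050,
     #  M     N     P     Q     R     S     T     V     W     Y
     0.015, 0.055, 0.100, 0.075, 0.055, 0.110, 0.065, 0.025, 0.005, 0.005]
)

UNIFORM_COMPOSITION = np.full(20, 0.05)


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to plant: pattern, selection strength, gain node, placement."""

    pattern: MotifPattern
    sigma: float
    gain_leaves: Optional[frozenset[str]] = None  # None => gained at the root
    position: Optional[int] = None  # 0-based start; None => random non-overlapping

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise InputError("selection strength sigma must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated proteome."""

    tree_newick: str = DEFAULT_TREE
    reference_species: str = DEFAULT_REFERENCE
    tree_scale: float = 1.0
    n_proteins: int = 100
    length_range: tuple[int, int] = (200, 500)
    composition: Optional[np.ndarray] = None  # None => uniform
    n_docking_planted: int = 0
    docking_sigma: float = 1.0
    co_occurrence_fraction: float = 0.0  # docking-planted proteins also given a consensus plant
    consensus_sigma: float = 1.0
    annotation_tp_rate: float = 0.8
    annotation_fp_rate: float = 0.01
    deletion_rate: float = 0.0  # per site per branch; >0 writes gapped alignments
    seed: int = 0

    def get_composition(self) -> np.ndarray:
        comp = UNIFORM_COMPOSITION if self.composition is None else np.asarray(self.composition)
        if comp.shape != (20,) or not math.isclose(comp.sum(), 1.0, abs_tol=1e-9):
            raise InputError("composition must be 20 frequencies summing to 1")
        return comp

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["composition"] = None if self.composition is None else list(map(float, self.composition))
        d["length_range"] = list(self.length_range)
        return d


@dataclass(frozen=True)
class PlantedTruth:
    protein_id: str
    pattern_label: str
    start: int  # 0-based in the (ungapped) root/reference coordinate frame
    sigma: float
    gain_leaves: str  # comma-joined leaf signature of the gain node


def _class_indices(cls: frozenset[str]) -> np.ndarray:
    return np.array(sorted(AMINO_ACIDS.index(a) for a in cls))


def _draw_from_class(cls: frozenset[str], comp: np.ndarray, rng: np.random.Generator) -> int:
    idx = _class_indices(cls)
    w = comp[idx]
    return int(rng.choice(idx, p=w / w.sum()))


def _plant(seq: np.ndarray, spec: PlantedMotif, start: int, comp: np.ndarray,
           rng: np.random.Generator) -> None:
    for offset, cls in enumerate(spec.pattern.positions):
        if len(cls) < 20:
            seq[start + offset] = _draw_from_class(cls, comp, rng)


def _choose_positions(
    specs: Sequence[PlantedMotif], length: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping start positions, honoring any explicit placements."""
    taken: list[tuple[int, int]] = []
    positions: list[int] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < e0 and s0 < e for s0, e0 in taken)

    for spec in specs:
        w = spec.pattern.width
        if length < w:
            raise InputError(f"protein length {length} below pattern width {w}")
        if spec.position is not None:
            s = spec.position
            if s < 0 or s + w > length:
                raise InputError(f"planted position {s} out of range")
            if overlaps(s, s + w):
                raise InputError(f"planted motif at {s} overlaps another planted motif")
        else:
            for _ in range(200):
                s = int(rng.integers(0, length - w + 1))
                if not overlaps(s, s + w):
                    break
            else:
                raise InputError("could not place planted motif without overlap")
        taken.append((s, s + w))
        positions.append(s)
    return positions


GAP_CODE = -1


def evolve_family(
    tree: dendropy.Tree,
    length: int,
    composition: np.ndarray,
    planted: Sequence[PlantedMotif],
    rng: np.random.Generator,
    reference_species: str = DEFAULT_REFERENCE,
    protein_id: str = "P0001",
    tree_scale: float = 1.0,
    deletion_rate: float = 0.0,
) -> tuple[OrthologGroup, list[PlantedTruth]]:
    """Evolve one family down the tree; returns the group and planted truth.

    With ``deletion_rate == 0`` (default) there are no indels, so the leaf
    sequences stack into a trivially exact alignment; otherwise
    geometric-length deletion runs introduce inherited gap columns.
    """
    comp = composition
    positions = _choose_positions(planted, length, rng)
    leaf_sets = {}
    for spec in planted:
        if spec.gain_leaves is None:
            leaf_sets[spec] = None  # root
        else:
            leaf_sets[spec] = set(spec.gain_leaves)
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}

    def gain_node(spec: PlantedMotif) -> dendropy.Node:
        if leaf_sets[spec] is None:
            return tree.seed_node
        missing = leaf_sets[spec] - taxa
        if missing:
            raise InputError(f"gain leaves {sorted(missing)} not in tree")
        if len(leaf_sets[spec]) == 1:
            (label,) = leaf_sets[spec]
            return next(l for l in tree.leaf_node_iter() if l.taxon.label == label)
        return tree.mrca(taxa=[l.taxon for l in tree.leaf_node_iter()
                               if l.taxon.label in leaf_sets[spec]])

    gains = {spec: gain_node(spec) for spec in planted}

    seqs: dict[dendropy.Node, np.ndarray] = {}
    active: dict[dendropy.Node, list[tuple[PlantedMotif, int]]] = {}
    root = tree.seed_node
    root_seq = rng.choice(20, size=length, p=comp).astype(np.int8)
    root_active = []
    for spec, start in zip(planted, positions):
        if gains[spec] is root:
            _plant(root_seq, spec, start, comp, rng)
            root_active.append((spec, start))
    seqs[root] = root_seq
    active[root] = root_active

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        b = (node.edge.length or 0.0) * tree_scale
        if b < 0:
            raise InputError("negative branch length")
        parent_seq = seqs[parent]
        p_sub = 1.0 - math.exp(-b)
        sub_mask = rng.random(length) < p_sub
        proposal = rng.choice(20, size=length, p=comp).astype(np.int8)
        child = np.where(sub_mask, proposal, parent_seq).astype(np.int8)
        gap_mask = parent_seq == GAP_CODE
        child[gap_mask] = GAP_CODE
        # Selection at constrained planted positions active below the gain node.
        for spec, start in active[parent]:
            if spec.sigma == 0.0:
                continue
            for offset, cls in enumerate(spec.pattern.positions):
                pos = start + offset
                if len(cls) == 20 or not sub_mask[pos] or gap_mask[pos]:
                    continue
                if child[pos] not in _class_indices(cls):
                    if rng.random() < spec.sigma:
                        child[pos] = parent_seq[pos]
        if deletion_rate > 0.0:
            child = _apply_deletions(child, deletion_rate * max(b, 0.0), rng,
                                     active[parent], length)
        node_active = list(active[parent])
        for spec, start in zip(planted, positions):
            if gains[spec] is node:
                _plant(child, spec, start, comp, rng)
                node_active.append((spec, start))
        seqs[node] = child
        active[node] = node_active

    rows = {}
    protein_ids = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        arr = seqs[leaf]
        chars = np.where(arr == GAP_CODE, b"-", AA_ARRAY[np.clip(arr, 0, 19)])
        rows[label] = b"".join(chars.tolist()).decode()
        protein_ids[label] = protein_id
    group = OrthologGroup(
        reference_id=protein_id,
        reference_species=reference_species,
        rows=rows,
        protein_ids=protein_ids,
    )
    truth = [
        PlantedTruth(
            protein_id=protein_id,
            pattern_label=spec.pattern.label,
            start=start,
            sigma=spec.sigma,
            gain_leaves=",".join(
                sorted(l.taxon.label for l in gains[spec].leaf_iter())
            ),
        )
        for spec, start in zip(planted, positions)
    ]
    return group, truth


def _apply_deletions(
    child: np.ndarray,
    expected_events_per_site: float,
    rng: np.random.Generator,
    active: list[tuple[PlantedMotif, int]],
    length: int,
) -> np.ndarray:
    """Geometric-length deletion runs; selection-protected planted columns."""
    protected = np.zeros(length, dtype=bool)
    for spec, start in active:
        if spec.sigma > 0.0:
            protected[start : start + spec.pattern.width] = True
    starts = np.flatnonzero(rng.random(length) < expected_events_per_site)
    for s in starts:
        run = int(rng.geometric(0.5))
        sl = slice(s, min(length, s + run))
        keep = protected[sl]
        segment = child[sl].copy()
        segment[~keep] = GAP_CODE
        child[sl] = segment
    return child


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_proteome` (optionally written out)."""

    config: SimulationConfig
    tree: dendropy.Tree
    proteome: list[ProteomeRecord]
    groups: list[OrthologGroup]
    truth: pd.DataFrame
    annotations: pd.DataFrame

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        (outdir / "groups").mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}

        proteome_path = outdir / "proteome.fasta"
        with open(proteome_path, "w") as fh:
            for rec in self.proteome:
                fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
        files["proteome"] = proteome_path

        index_rows = []
        for group in self.groups:
            gpath = outdir / "groups" / f"{group.reference_id}.fasta"
            with open(gpath, "w") as fh:
                for sp, row in group.rows.items():
                    fh.write(f">{sp}|{group.protein_ids[sp]}\n{row}\n")
            index_rows.append((group.reference_id, f"groups/{group.reference_id}.fasta"))
            files[f"group:{group.reference_id}"] = gpath
        index_path = outdir / "groups.tsv"
        pd.DataFrame(index_rows, columns=["reference_id", "path"]).to_csv(
            index_path, sep="\t", index=False
        )
        files["group_index"] = index_path

        tree_path = outdir / "tree.nwk"
        tree_path.write_text(self.config.tree_newick.strip() + "\n")
        files["tree"] = tree_path

        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        files["truth"] = truth_path

        ann_path = outdir / "annotations.tsv"
        self.annotations.to_csv(ann_path, sep="\t", index=False)
        files["annotations"] = ann_path

        manifest = {
            "config": self.config.to_jsonable(),
            "hashes": {
                name: hashlib.sha256(path.read_bytes()).hexdigest()
                for name, path in sorted(files.items())
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def simulate_proteome(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a proteome of ortholog families with planted-motif truth.

    The first ``n_docking_planted`` proteins receive a docking-motif plant
    (selection ``docking_sigma``); of these, the first
    ``round(co_occurrence_fraction * n_docking_planted)`` also receive a
    consensus plant — the dual-motif proteins Fig-7-style discovery should
    find. The annotation table marks planted consensus acceptors as
    phosphorylated with rate ``annotation_tp_rate`` and sprinkles false
    positives on other S/T residues at ``annotation_fp_rate``.
    """
    rng = np.random.default_rng(config.seed)
    tree = read_species_tree(config.tree_newick)
    comp = config.get_composition()
    lo, hi = config.length_range
    docking = PATTERNS["docking"]
    consensus = PATTERNS["consensus"]
    if config.n_docking_planted > config.n_proteins:
        raise InputError("more planted proteins than proteins")
    n_dual = int(round(config.co_occurrence_fraction * config.n_docking_planted))

    groups: list[OrthologGroup] = []
    proteome: list[ProteomeRecord] = []
    truth_rows: list[PlantedTruth] = []
    for i in range(config.n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        planted: list[PlantedMotif] = []
        if i < config.n_docking_planted:
            planted.append(PlantedMotif(docking, config.docking_sigma))
            if i < n_dual:
                planted.append(PlantedMotif(consensus, config.consensus_sigma))
        group, truth = evolve_family(
            tree,
            length,
            comp,
            planted,
            rng,
            reference_species=config.reference_species,
            protein_id=pid,
            tree_scale=config.tree_scale,
            deletion_rate=config.deletion_rate,
        )
        groups.append(group)
        proteome.append(ProteomeRecord(pid, group.ungapped(config.reference_species)))
        truth_rows.extend(truth)

    truth_df = pd.DataFrame(
        [t.__dict__ for t in truth_rows],
        columns=["protein_id", "pattern_label", "start", "sigma", "gain_leaves"],
    )
    annotations = _make_annotations(proteome, truth_df, consensus, config, rng)
    return SimulatedDataset(
        config=config,
        tree=tree,
        proteome=proteome,
        groups=groups,
        truth=truth_df,
        annotations=annotations,
    )


def _make_annotations(
    proteome: Sequence[ProteomeRecord],
    truth: pd.DataFrame,
    consensus: MotifPattern,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    planted_acceptors: set[tuple[str, int]] = set()
    cons_truth = truth[truth["pattern_label"] == consensus.label]
    for pid, start in cons_truth[["protein_id", "start"]].itertuples(index=False):
        planted_acceptors.add((str(pid), int(start) + consensus.width))  # 1-based acceptor
    rows = []
    for rec in proteome:
        for pos0, residue in enumerate(rec.sequence):
            pos1 = pos0 + 1
            if (rec.protein_id, pos1) in planted_acceptors:
                if rng.random() < config.annotation_tp_rate:
                    rows.append((rec.protein_id, pos1))
            elif residue in "ST":
                if rng.random() < config.annotation_fp_rate:
                    rows.append((rec.protein_id, pos1))
    return pd.DataFrame(rows, columns=["protein_id", "position_1based"])


@dataclass
class CalibrationResult:
    alpha: float
    n_families: int
    n_rejected: int
    n_simulated: int

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_families


def calibration_run(
    n_families: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> CalibrationResult:
    """Empirical type-I error of the conservation score under neutrality.

    Families carry a root-planted docking motif with ``sigma = 0`` (no
    selection). Whenever the reference still matches the pattern at the
    planted window, that match is scored and its combined p compared with
    ``alpha``; families whose reference lost the motif carry no testable
    match and are redrawn until ``n_families`` scores are collected.
    """
    if n_families < 1:
        raise InputError("need at least one family")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    tree = read_species_tree(cfg.tree_newick)
    phylo_null = PhyloRetentionNull(tree, cfg.reference_species)
    comp = cfg.get_composition()
    docking = PATTERNS["docking"]
    lo, hi = cfg.length_range
    scored = 0
    rejected = 0
    attempts = 0
    max_attempts = 50 * n_families
    while scored < n_families:
        attempts += 1
        if attempts > max_attempts:
            raise InputError("reference retained the neutral motif too rarely")
        length = int(rng.integers(lo, hi + 1))
        spec = PlantedMotif(docking, sigma=0.0)
        group, truth = evolve_family(
            tree, length, comp, [spec], rng,
            reference_species=cfg.reference_species,
            tree_scale=cfg.tree_scale,
        )
        start = truth[0].start
        ref_seq = group.ungapped(cfg.reference_species)
        if not docking.matches_at(ref_seq, start):
            continue
        null = NullModel.from_group(group, docking)
        match = MotifMatch(
            protein_id=group.reference_id,
            start=start,
            end=start + docking.width,
            matched_seq=ref_seq[start : start + docking.width],
            pattern_label=docking.label,
        )
        result = score_match(match, docking, group, null, phylo_null)
        scored += 1
        if result.combined_p <= alpha:
            rejected += 1
    return CalibrationResult(alpha, n_families, rejected, attempts)


@dataclass
class AncestryRecoveryResult:
    n_families: int
    n_recovered: int
    n_with_losses_checked: int
    n_within_true_subtree: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_families if self.n_families else float("nan")


def ancestry_recovery_run(
    n_families: int = 500,
    seed: int = 0,
    sigma: float = 1.0,
    length: int = 60,
    tree_newick: str = DEFAULT_TREE,
    tree_scale: float = 1.0,
    reference_species: str = DEFAULT_REFERENCE,
) -> AncestryRecoveryResult:
    """Recovery of planted gain nodes by Dollo parsimony.

    Each family plants one docking motif at a random tree node (root,
    internal, or leaf). Families in which a species outside the gain clade
    carries a chance background match are redrawn: the experiment tests
    gain placement given the presence calls, not the scanner's false
    positive rate (the null-calibration run covers that). With
    ``sigma = 1`` no losses occur and the inferred gain must equal the
    planted node; with ``sigma < 1`` lineages may lose the motif and the
    inferred gain is checked to stay within the planted node's subtree.
    """
    from .ancestry import dollo_gain, leaf_presence

    tree = read_species_tree(tree_newick)
    comp = UNIFORM_COMPOSITION
    docking = PATTERNS["docking"]
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder_node_iter())
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    recovered = 0
    checked = losses_ok = 0
    produced = 0
    attempts = 0
    while produced < n_families:
        attempts += 1
        if attempts > 100 * n_families:
            raise InputError("too many rejected families in ancestry recovery run")
        node = nodes[int(rng.integers(len(nodes)))]
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        spec = PlantedMotif(docking, sigma=sigma, gain_leaves=clade)
        group, truth = evolve_family(
            tree, length, comp, [spec], rng,
            reference_species=reference_species, tree_scale=tree_scale,
        )
        start = truth[0].start
        profile = leaf_presence(group, docking, species)
        # Redraw on chance matches outside the gain clade.
        outside = {sp for sp in profile.presence_leaves if sp not in clade}
        if outside:
            continue
        if not profile.presence_leaves:
            continue  # full loss (possible when sigma < 1): nothing to place
        produced += 1
        event = dollo_gain(tree, profile)
        true_leaves = clade
        inferred_leaves = event.leaf_signature
        if inferred_leaves == true_leaves:
            recovered += 1
        checked += 1
        if inferred_leaves <= true_leaves:
            losses_ok += 1
    return AncestryRecoveryResult(
        n_families=produced,
        n_recovered=recovered,
        n_with_losses_checked=checked,
        n_within_true_subtree=losses_ok,
    )


@dataclass
class PowerResult:
    n_proteins: int
    n_planted: int
    n_recovered: int
    n_dual_planted: int
    n_dual_flagged: int
    top_k: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def power_run(
    n_proteins: int = 5000,
    n_planted: int = 50,
    n_dual: int = 6,
    seed: int = 0,
    tree_scale: float = 3.0,
    top_k: Optional[int] = None,
    config: Optional[SimulationConfig] = None,
) -> tuple[PowerResult, pd.DataFrame]:
    """Recovery of selection-maintained plants by the top-k score list.

    ``n_planted`` proteins carry a sigma = 1 docking plant (of which
    ``n_dual`` also carry a consensus plant); the rest are background. All
    proteins with at least one reference match are scored; recovery is the
    fraction of planted proteins inside the top-``n_planted`` docking
    score list, and the dual plants must be flagged by the dual-rule
    scatter. Returns the metrics and the scatter table.
    """
    from .cooccur import TopK, coconservation_scatter
    from .scoring import protein_motif_score

    base = config or SimulationConfig()
    cfg = replace(
        base,
        n_proteins=n_proteins,
        n_docking_planted=n_planted,
        co_occurrence_fraction=(n_dual / n_planted) if n_planted else 0.0,
        docking_sigma=1.0,
        consensus_sigma=1.0,
        tree_scale=tree_scale,
        seed=seed,
    )
    data = simulate_proteome(cfg)
    phylo_null = PhyloRetentionNull(data.tree, cfg.reference_species)
    docking = PATTERNS["docking"]
    consensus = PATTERNS["consensus"]
    dock_scores: dict[str, float] = {}
    cons_scores: dict[str, float] = {}
    for group in data.groups:
        for pattern, store in ((docking, dock_scores), (consensus, cons_scores)):
            ps = protein_motif_score(group, pattern, phylo_null=phylo_null)
            if ps is not None:
                store[ps.protein_id] = ps.best_score

    k = top_k if top_k is not None else max(n_planted, 1)
    planted_ids = {
        f"P{i:04d}" for i in range(n_planted)
    }
    dual_ids = {f"P{i:04d}" for i in range(int(round(cfg.co_occurrence_fraction * n_planted)))}
    from .cooccur import classify_conserved

    top = classify_conserved(dock_scores, TopK(min(k, len(dock_scores)))) if dock_scores else set()
    scatter = coconservation_scatter(
        dock_scores,
        cons_scores,
        TopK(min(k, len(dock_scores))) if dock_scores else TopK(1),
        TopK(min(k, len(cons_scores))) if cons_scores else TopK(1),
    )
    flagged = set(scatter.loc[scatter["both_conserved"], "protein_id"])
    result = PowerResult(
        n_proteins=n_proteins,
        n_planted=n_planted,
        n_recovered=len(planted_ids & top),
        n_dual_planted=len(dual_ids),
        n_dual_flagged=len(dual_ids & flagged),
        top_k=k,
    )
    return result, scatter
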