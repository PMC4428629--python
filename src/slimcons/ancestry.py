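"""Acquisition-order inference for motif classes on a species tree.

Presence of each motif class per species (at least one raw scan match in
that species' ortholog) is mapped onto the species tree, the gain placed
by Dollo parsimony (a single gain at the MRCA of the presence leaves,
losses as needed — short degenerate motifs are far easier to lose than to
gain twice), and the relative placement of the two gains classified:
phospho-first, simultaneous, dock-first, or undetermined when the gain
nodes are not ancestrally comparable. Species with no ortholog available
are treated as missing data, not absence, so they neither pull the gain
deeper nor count as losses.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd

from .errors import InputError
from .motifs import MotifPattern, scan_sequence
from .orthologs import OrthologGroup


@dataclass
class PresenceProfile:
    """Leaf-level presence flags for one motif class in one family."""

    motif_label: str
    present: dict[str, bool]
    missing: set[str] = field(default_factory=set)

    @property
    def presence_leaves(self) -> set[str]:
        return {sp for sp, flag in self.present.items() if flag}


def leaf_presence(
    group: OrthologGroup,
    pattern: MotifPattern,
    species: Iterable[str],
) -> PresenceProfile:
    """Presence = at least one match in the species' ungapped sequence.

    Species without a row in the group are flagged missing (excluded from
    gain inference rather than scored as absent).
    """
    present: dict[str, bool] = {}
    missing: set[str] = set()
    for sp in species:
        if sp not in group.rows:
            missing.add(sp)
            continue
        present[sp] = bool(scan_sequence(pattern, group.ungapped(sp), sp))
    return PresenceProfile(motif_label=pattern.label, present=present, missing=missing)


@dataclass
class GainEvent:
    """A single Dollo gain: the node where the motif arose, plus loss count."""

    node: dendropy.Node
    motif_label: str
    n_losses: int

    @property
    def leaf_signature(self) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in self.node.leaf_iter())


def _leaf_nodes(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def dollo_gain(tree: dendropy.Tree, profile: PresenceProfile) -> GainEvent:
    """Place a single gain at the MRCA of all presence leaves.

    The loss count is the minimal number of loss edges below the gain
    node needed to explain absent leaves; missing-data leaves never force
    a loss.
    """
    leaves = _leaf_nodes(tree)
    unknown = (set(profile.present) | profile.missing) - set(leaves)
    if unknown:
        raise InputError(f"species {sorted(unknown)} not in the species tree")
    presence = profile.presence_leaves
    if not presence:
        raise InputError("empty presence set: no gain to place")
    if len(presence) == 1:
        gain = leaves[next(iter(presence))]
    else:
        gain = tree.mrca(taxa=[leaves[sp].taxon for sp in presence])

    # Post-order state propagation below the gain node: a subtree is
    # 'absent' when every informative leaf in it lacks the motif.
    PRESENT, ABSENT, MISSING = 0, 1, 2
    state: dict[dendropy.Node, int] = {}
    for node in gain.postorder_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in presence:
                state[node] = PRESENT
            elif label in profile.missing or label not in profile.present:
                state[node] = MISSING
            else:
                state[node] = ABSENT
        else:
            child_states = [state[c] for c in node.child_nodes()]
            if PRESENT in child_states:
                state[node] = PRESENT
            elif ABSENT in child_states:
                state[node] = ABSENT
            else:
                state[node] = MISSING
    n_losses = 0
    for node in gain.preorder_iter():
        if state[node] == PRESENT:
            n_losses += sum(1 for c in node.child_nodes() if state[c] == ABSENT)
    return GainEvent(node=gain, motif_label=profile.motif_label, n_losses=n_losses)


class OrderingCall(str, Enum):
    PHOSPHO_FIRST = "phospho_first"
    SIMULTANEOUS = "simultaneous"
    DOCK_FIRST = "dock_first"
    UNDETERMINED = "undetermined"
    NO_CALL = "no_call"


def _is_proper_ancestor(node_a: dendropy.Node, node_b: dendropy.Node) -> bool:
    parent = node_b.parent_node
    while parent is not None:
        if parent is node_a:
            return True
        parent = parent.parent_node
    return False


def order_call(
    gain_dock: Optional[GainEvent],
    gain_consensus: Optional[GainEvent],
    tree: dendropy.Tree,
) -> OrderingCall:
    """Classify the relative placement of the two gain nodes."""
    if gain_dock is None or gain_consensus is None:
        return OrderingCall.NO_CALL
    dock, cons = gain_dock.node, gain_consensus.node
    if dock is cons:
        return OrderingCall.SIMULTANEOUS
    if _is_proper_ancestor(cons, dock):
        return OrderingCall.PHOSPHO_FIRST
    if _is_proper_ancestor(dock, cons):
        return OrderingCall.DOCK_FIRST
    return OrderingCall.UNDETERMINED


def cohort_summary(calls: Mapping[str, OrderingCall]) -> dict:
    """Tally ordering calls over families; lists any dock-first families."""
    tally = Counter(call.value for call in calls.values())
    for kind in OrderingCall:
        tally.setdefault(kind.value, 0)
    dock_first = sorted(fam for fam, call in calls.items() if call is OrderingCall.DOCK_FIRST)
    return {
        "counts": dict(tally),
        "dock_first_families": dock_first,
        "dock_first_flag": bool(dock_first),
    }


FAMILY_TABLE_COLUMNS = (
    "reference_id",
    "dock_gain_postorder",
    "dock_gain_leaves",
    "dock_losses",
    "consensus_gain_postorder",
    "consensus_gain_leaves",
    "consensus_losses",
    "ordering",
)


def analyze_cohort(
    groups: Iterable[OrthologGroup],
    tree: dendropy.Tree,
    docking: MotifPattern,
    consensus: MotifPattern,
) -> tuple[pd.DataFrame, dict]:
    """Per-family gain placement and ordering calls, plus the cohort tally."""
    postorder_index = {node: i for i, node in enumerate(tree.postorder_node_iter())}
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rows = []
    calls: dict[str, OrderingCall] = {}
    for group in groups:
        events: dict[str, Optional[GainEvent]] = {}
        for pattern in (docking, consensus):
            profile = leaf_presence(group, pattern, species)
            events[pattern.label] = (
                dollo_gain(tree, profile) if profile.presence_leaves else None
            )
        call = order_call(events[docking.label], events[consensus.label], tree)
        calls[group.reference_id] = call

        def describe(event: Optional[GainEvent]) -> tuple[int, str, int]:
            if event is None:
                return -1, "", -1
            return (
                postorder_index[event.node],
                ",".join(sorted(event.leaf_signature)),
                event.n_losses,
            )
        d_idx, d_sig, d_loss = describe(events[docking.label])
        c_idx, c_sig, c_loss = describe(events[consensus.label])
        rows.append((group.reference_id, d_idx, d_sig, d_loss, c_idx, c_sig, c_loss, call.value))
    table = pd.DataFrame(rows, columns=FAMILY_TABLE_COLUMNS)
    return table, cohort_summary(calls)


def write_cohort(table: pd.DataFrame, summary: dict, tsv_path, json_path) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
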