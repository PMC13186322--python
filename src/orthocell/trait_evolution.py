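"""Maximum-parsimony reconstruction of binary trait evolution on a dated tree.

Each orthogroup's activity (1 = up-regulated in the focal phagocyte-like
cell types, 0 = not) is a binary character observed at the tips of a rooted
species tree with branch lengths in millions of years (Myr).  Ancestral
states are inferred by minimizing the number of state transitions:

* a bottom-up unit-cost Sankoff pass (the Fitch algorithm generalized to
  multifurcations) yields per-node candidate state sets and the parsimony
  score;
* a top-down ACCTRAN-style pass resolves ambiguity by inheriting the
  parent's state whenever it is among a node's candidates, with root ties
  broken toward state 1 (active) and logged — the resolved assignment always
  attains the parsimony score;
* transitions are tallied per branch as gains (0 -> 1) and losses (1 -> 0)
  and converted to rates, transitions per Myr of branch length.

Internal nodes are addressed by their Newick label when present and always
by their tip-set signature, e.g. ``MRCA(oyster,human)``.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "node_name",
    "fitch_states",
    "resolve_states_acctran",
    "count_transitions",
    "branch_change_rates",
    "ancestral_active_set",
    "reconstruct_trait_evolution",
    "TraitReconstruction",
]

_INF = 10 ** 9


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree (branch lengths in Myr) from path or string.

    Tips must be named.  A basal trifurcation (the usual serialization of an
    unrooted tree) is accepted as a multifurcating root and logged.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValidationError("tree contains an unnamed tip")
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        logger.info(
            "root has %d children; treated as a multifurcation",
            len(root_children),
        )
    return tree


def node_name(node: dendropy.Node) -> str:
    """Stable node address: tip name, Newick label, or MRCA tip signature."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    tips = sorted(l.taxon.label for l in node.leaf_iter())
    return "MRCA(" + ",".join(tips) + ")"


def _find_node(tree: dendropy.Tree, name: str) -> dendropy.Node:
    if name == "root":
        return tree.seed_node
    for node in tree.preorder_node_iter():
        if node_name(node) == name or (node.label == name):
            return node
    raise ValidationError(f"no node named {name!r} in tree")


def _sankoff_costs(tree: dendropy.Tree,
                   tip_states: Mapping[str, int]) -> dict:
    """Bottom-up unit-cost Sankoff pass; per-node cost for states 0 and 1."""
    costs: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_states:
                raise ValidationError(f"missing tip state for {label!r}")
            s = int(tip_states[label])
            if s not in (0, 1):
                raise ValidationError(f"tip state for {label!r} must be 0 or 1")
            c = np.array([_INF, _INF])
            c[s] = 0
        else:
            c = np.zeros(2, dtype=np.int64)
            for child in node.child_nodes():
                cc = costs[child]
                # min over child state t of cost + unit substitution penalty
                c += np.minimum(cc, cc[::-1] + 1)
        costs[node] = c
    return costs


def fitch_states(tree: dendropy.Tree, tip_states: Mapping[str, int]):
    """Parsimony candidate state sets and minimum number of changes.

    Returns ``(sets, score)`` where ``sets`` maps each node to the frozenset
    of states attaining the minimal subtree cost at that node, and ``score``
    is the minimum number of transitions over the whole tree.
    """
    costs = _sankoff_costs(tree, tip_states)
    sets = {
        node: frozenset(s for s in (0, 1) if c[s] == c.min())
        for node, c in costs.items()
    }
    score = int(costs[tree.seed_node].min())
    return sets, score


def resolve_states_acctran(tree: dendropy.Tree,
                           fitch_sets: Mapping[dendropy.Node, frozenset]
                           ) -> dict[dendropy.Node, int]:
    """Resolve candidate sets to one state per node, top-down.

    Each node takes the parent's state when it lies in the node's candidate
    set, otherwise its unique candidate; the root breaks a {0, 1} tie toward
    state 1 (active), which is logged.  The resolved assignment attains the
    parsimony score.
    """
    resolved: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        cand = fitch_sets[node]
        if node.parent_node is None:
            if len(cand) > 1:
                logger.debug("root parsimony tie broken toward state 1")
                resolved[node] = 1
            else:
                resolved[node] = next(iter(cand))
        else:
            parent = resolved[node.parent_node]
            resolved[node] = parent if parent in cand else next(iter(cand))
    return resolved


def count_transitions(tree: dendropy.Tree,
                      resolved: Mapping[str, Mapping[dendropy.Node, int]]
                      ) -> pd.DataFrame:
    """Per-branch gains (0 -> 1) and losses (1 -> 0) summed over traits.

    ``resolved`` maps each trait (OG id) to its resolved node states.  The
    returned frame is indexed by the branch's child node name with columns
    ``gains``, ``losses`` and ``length`` (Myr; NaN when missing).
    """
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    gains = {n: 0 for n in edges}
    losses = {n: 0 for n in edges}
    for states in resolved.values():
        for n in edges:
            parent, child = states[n.parent_node], states[n]
            if parent == 0 and child == 1:
                gains[n] += 1
            elif parent == 1 and child == 0:
                losses[n] += 1
    return pd.DataFrame(
        {
            "gains": [gains[n] for n in edges],
            "losses": [losses[n] for n in edges],
            "length": [np.nan if n.edge.length is None else float(n.edge.length)
                       for n in edges],
        },
        index=pd.Index([node_name(n) for n in edges], name="branch"),
    )


def branch_change_rates(counts: pd.DataFrame) -> pd.Series:
    """Transitions per Myr: (gains + losses) / branch length.

    Branches with missing or non-positive length get NaN with a warning.
    """
    length = counts["length"]
    bad = ~(length > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} branches have missing or non-positive length; "
            "their rates are reported as missing"
        )
    rate = (counts["gains"] + counts["losses"]).where(~bad) / length.where(~bad)
    rate.name = "rate_per_myr"
    return rate


@dataclass
class TraitReconstruction:
    """Bundle of a full multi-trait parsimony reconstruction."""

    tree: dendropy.Tree
    node_states: pd.DataFrame     # nodes x OGs, resolved 0/1
    scores: pd.Series             # per-OG parsimony score
    edge_counts: pd.DataFrame     # per-branch gains/losses/length
    rates: pd.Series              # per-branch transitions per Myr

    def active_set(self, node: str) -> frozenset:
        """OGs with resolved state 1 at the named node."""
        if node not in self.node_states.index:
            raise ValidationError(f"no node named {node!r} in reconstruction")
        row = self.node_states.loc[node]
        return frozenset(row.index[row == 1])

    def annotated_newick(self) -> str:
        """Newick string with per-branch rates as node comments."""
        tree = self.tree.clone(depth=1)
        for n in tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            name = node_name(n)
            if name in self.rates.index and not np.isnan(self.rates[name]):
                n.annotations.add_new("rate_per_myr",
                                      f"{self.rates[name]:.6g}")
        s = _io.StringIO()
        tree.write(file=s, schema="newick", suppress_annotations=False)
        return s.getvalue()


def reconstruct_trait_evolution(tree: dendropy.Tree,
                                activity: pd.DataFrame) -> TraitReconstruction:
    """Reconstruct all traits of a species x OG binary activity matrix.

    ``activity`` rows are species (matching tip names), columns OGs, values
    0/1.  Runs the Sankoff + ACCTRAN passes per OG, tallies per-branch
    transitions and rates.
    """
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = tips.difference(activity.index)
    if missing:
        raise ValidationError(f"activity matrix lacks species {sorted(missing)}")
    resolved: dict[str, dict[dendropy.Node, int]] = {}
    scores = {}
    n_root_ties = 0
    for og in activity.columns:
        tip_states = activity[og].to_dict()
        sets, score = fitch_states(tree, tip_states)
        n_root_ties += int(len(sets[tree.seed_node]) > 1)
        resolved[og] = resolve_states_acctran(tree, sets)
        scores[og] = score
    if n_root_ties:
        logger.info(
            "%d of %d traits had a root parsimony tie, broken toward "
            "state 1 (active)", n_root_ties, len(activity.columns),
        )
    counts = count_transitions(tree, resolved)
    rates = branch_change_rates(counts)
    nodes = list(tree.preorder_node_iter())
    node_states = pd.DataFrame(
        {og: [resolved[og][n] for n in nodes] for og in activity.columns},
        index=pd.Index([node_name(n) for n in nodes], name="node"),
    )
    return TraitReconstruction(
        tree=tree,
        node_states=node_states,
        scores=pd.Series(scores, name="parsimony_score"),
        edge_counts=counts,
        rates=rates,
    )


def ancestral_active_set(activity: pd.DataFrame, tree: dendropy.Tree,
                         node: str) -> frozenset:
    """OGs reconstructed as active (state 1) at the named internal node."""
    _find_node(tree, node)  # fail early with a clear message
    rec = reconstruct_trait_evolution(tree, activity)
    name = "root" if node == "root" else node
    if name == "root":
        name = node_name(tree.seed_node)
    return rec.active_set(name)
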