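"""Parsimony reconstruction: Fitch/Sankoff scores, ACCTRAN resolution,
transition counting and per-Myr rates."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from orthocell import (ValidationError, ancestral_active_set,
                       branch_change_rates, count_transitions, fitch_states,
                       read_newick, reconstruct_trait_evolution,
                       resolve_states_acctran)
from orthocell.trait_evolution import node_name


def random_tree(rng, n_tips, multifurcate=False):
    """Random rooted tree over named tips by sequential joining."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        leaf = dendropy.Node()
        leaf.taxon = taxa.new_taxon(f"t{i}")
        leaf.edge.length = float(rng.integers(1, 50))
        nodes.append(leaf)
    while len(nodes) > 1:
        k = 2
        if multifurcate and len(nodes) > 2 and rng.random() < 0.3:
            k = 3
        picks = rng.choice(len(nodes), size=k, replace=False)
        parent = dendropy.Node()
        parent.edge.length = float(rng.integers(1, 50))
        for j in sorted(picks, reverse=True):
            parent.add_child(nodes.pop(j))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def brute_force_parsimony(tree, tip_states):
    """Minimum changes over all 2^(#internal) assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = dict(zip(internals, assignment))
        for leaf in tree.leaf_node_iter():
            states[leaf] = tip_states[leaf.taxon.label]
        changes = sum(
            1
            for n in tree.preorder_node_iter()
            if n.parent_node is not None and states[n] != states[n.parent_node]
        )
        best = changes if best is None else min(best, changes)
    return best


def count_resolved_changes(tree, resolved):
    return sum(
        1
        for n in tree.preorder_node_iter()
        if n.parent_node is not None and resolved[n] != resolved[n.parent_node]
    )


class TestReadNewick:
    def test_parse_tips_and_lengths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):2,C:3);\n")
        tree = read_newick(p)
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert tips == ["A", "B", "C"]
        lengths = sorted(
            n.edge.length for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        assert lengths == [1.0, 1.0, 2.0, 3.0]

    def test_round_trip_preserves_topology_and_lengths(self):
        s = "((A:1.5,B:2.5):3,(C:4,D:5):6);"
        tree = read_newick(s)
        out = tree.as_string(schema="newick").strip()
        tree2 = read_newick(out[out.index("("):])
        assert (tree.as_string(schema="newick")
                == tree2.as_string(schema="newick"))

    def test_basal_trifurcation_accepted(self):
        tree = read_newick("(A:1,B:1,C:1);")
        assert len(tree.seed_node.child_nodes()) == 3


class TestFitch:
    def test_uniform_tips_score_zero(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sets, score = fitch_states(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert score == 0
        assert all(s == {1} for n, s in sets.items())

    def test_balanced_split_root_ambiguous(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sets, score = fitch_states(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert score == 1
        assert sets[tree.seed_node] == {0, 1}

    def test_missing_tip_state_names_tip(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValidationError, match="C"):
            fitch_states(tree, {"A": 1, "B": 0})

    @pytest.mark.parametrize("multifurcate", [False, True])
    def test_score_matches_exhaustive_oracle(self, multifurcate):
        rng = np.random.default_rng(101 + int(multifurcate))
        for _ in range(150):
            n_tips = int(rng.integers(3, 8))
            tree = random_tree(rng, n_tips, multifurcate=multifurcate)
            tip_states = {f"t{i}": int(rng.integers(0, 2))
                          for i in range(n_tips)}
            _, score = fitch_states(tree, tip_states)
            assert score == brute_force_parsimony(tree, tip_states)

    def test_score_invariant_under_state_relabeling(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tree = random_tree(rng, 6)
            tip_states = {f"t{i}": int(rng.integers(0, 2)) for i in range(6)}
            flipped = {k: 1 - v for k, v in tip_states.items()}
            assert fitch_states(tree, tip_states)[1] == \
                fitch_states(tree, flipped)[1]


class TestAcctran:
    def test_unambiguous_sets_pass_through(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sets, _ = fitch_states(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        resolved = resolve_states_acctran(tree, sets)
        assert all(v == 1 for v in resolved.values())

    def test_root_tie_broken_toward_active(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sets, score = fitch_states(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        resolved = resolve_states_acctran(tree, sets)
        assert resolved[tree.seed_node] == 1
        assert count_resolved_changes(tree, resolved) == score == 1
        # the single change is a loss on the (C,D) ancestor edge
        cd = next(n for n in tree.preorder_node_iter()
                  if not n.is_leaf() and
                  {l.taxon.label for l in n.leaf_iter()} == {"C", "D"})
        assert resolved[cd] == 0 and resolved[cd.parent_node] == 1

    def test_resolution_attains_parsimony_score_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n_tips = int(rng.integers(3, 8))
            tree = random_tree(rng, n_tips, multifurcate=bool(rng.integers(2)))
            tip_states = {f"t{i}": int(rng.integers(0, 2))
                          for i in range(n_tips)}
            sets, score = fitch_states(tree, tip_states)
            resolved = resolve_states_acctran(tree, sets)
            assert count_resolved_changes(tree, resolved) == score


class TestTransitionsAndRates:
    def test_no_change_all_zero(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        sets, _ = fitch_states(tree, {"A": 1, "B": 1, "C": 1})
        resolved = {"OG1": resolve_states_acctran(tree, sets)}
        counts = count_transitions(tree, resolved)
        assert (counts[["gains", "losses"]].to_numpy() == 0).all()

    def test_single_flip_single_counter(self):
        tree = read_newick("((A:10,B:10):10,C:10);")
        sets, _ = fitch_states(tree, {"A": 1, "B": 1, "C": 0})
        resolved = {"OG1": resolve_states_acctran(tree, sets)}
        counts = count_transitions(tree, resolved)
        assert counts["gains"].sum() + counts["losses"].sum() == 1

    def test_totals_equal_sum_of_parsimony_scores(self):
        rng = np.random.default_rng(19)
        tree = random_tree(rng, 7)
        resolved, total_score = {}, 0
        for og in range(25):
            tip_states = {f"t{i}": int(rng.integers(0, 2)) for i in range(7)}
            sets, score = fitch_states(tree, tip_states)
            resolved[f"OG{og}"] = resolve_states_acctran(tree, sets)
            total_score += score
        counts = count_transitions(tree, resolved)
        assert counts["gains"].sum() + counts["losses"].sum() == total_score

    def test_rate_is_transitions_per_myr(self):
        counts = pd.DataFrame(
            {"gains": [2, 0], "losses": [0, 0], "length": [100.0, 50.0]},
            index=["e1", "e2"],
        )
        rates = branch_change_rates(counts)
        assert rates["e1"] == pytest.approx(0.02)
        assert rates["e2"] == 0.0

    def test_doubling_lengths_halves_rates(self):
        counts = pd.DataFrame(
            {"gains": [3, 1], "losses": [1, 2], "length": [10.0, 20.0]},
            index=["e1", "e2"],
        )
        r1 = branch_change_rates(counts)
        doubled = counts.assign(length=counts["length"] * 2)
        r2 = branch_change_rates(doubled)
        np.testing.assert_allclose(r2, r1 / 2)

    def test_zero_length_branch_missing_rate_with_warning(self):
        counts = pd.DataFrame(
            {"gains": [1], "losses": [0], "length": [0.0]}, index=["e1"]
        )
        with pytest.warns(UserWarning, match="length"):
            rates = branch_change_rates(counts)
        assert np.isnan(rates["e1"])


class TestAncestralActiveSet:
    def test_trivial_membership(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        activity = pd.DataFrame(
            {"OG1": [1, 1, 1], "OG2": [0, 0, 0]},
            index=["A", "B", "C"],
        )
        root = node_name(tree.seed_node)
        active = ancestral_active_set(activity, tree, root)
        assert active == {"OG1"}

    def test_unknown_node_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        activity = pd.DataFrame({"OG1": [1, 1, 1]}, index=["A", "B", "C"])
        with pytest.raises(ValidationError, match="nope"):
            ancestral_active_set(activity, tree, "nope")

    def test_reconstruction_bundle_consistency(self):
        rng = np.random.default_rng(29)
        tree = random_tree(rng, 6)
        activity = pd.DataFrame(
            rng.integers(0, 2, size=(6, 40)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"OG{i}" for i in range(40)],
        )
        rec = reconstruct_trait_evolution(tree, activity)
        # conservation identity: branch transitions sum to total score
        assert (rec.edge_counts["gains"].sum()
                + rec.edge_counts["losses"].sum()) == rec.scores.sum()
        assert (rec.rates.dropna() >= 0).all()
        np.testing.assert_allclose(
            rec.rates.to_numpy(),
            ((rec.edge_counts["gains"] + rec.edge_counts["losses"])
             / rec.edge_counts["length"]).to_numpy(),
        )
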