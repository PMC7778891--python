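"""Parsimony placement: Fitch costs against exhaustive internal-state
enumeration, incremental edge costs against naive augmented-tree
recomputation, graft mechanics, tie handling, and jplace export."""

import itertools
import json

import numpy as np
import pytest

from phylograft import synthetic_data as synth
from phylograft.placement import (
    ROOT_EDGE,
    edge_placement_costs,
    edge_topological_distance,
    export_jplace,
    fitch_cost,
    graft,
)
from phylograft.profile import build_profile, score_and_align
from phylograft.reference_library import (
    FamilyBundle,
    FamilyMSA,
    TermAnnotationMap,
    TreeNode,
    parse_newick,
)


def enumerate_min_substitutions(tree, leaf_states) -> int:
    """Independent oracle: minimum substitution count over all assignments of
    observed states to internal nodes (optimal assignments never need states
    absent from the leaves)."""
    leaves = tree.leaves()
    internals = list(tree.internal_nodes())
    observed = sorted(set().union(*[set(leaf_states[l]) for l in leaves]))
    best = None
    for combo in itertools.product(observed, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        # leaves: best compatible state given parent is fixed; since leaf
        # state sets may have several members, pick min-cost member
        cost = 0
        for nid in tree.nodes:
            node = tree.nodes[nid]
            if node.parent is None:
                continue
            if tree.is_leaf(nid):
                parent_state = assign[node.parent]
                cost += 0 if parent_state in set(leaf_states[nid]) else 1
            else:
                cost += assign[nid] != assign[node.parent]
        if best is None or cost < best:
            best = cost
    return best


def naive_augmented_costs(bundle, aligned, query_seq):
    """Naive per-edge recomputation: physically graft on each edge and rerun
    the downpass from scratch on the augmented tree."""
    from phylograft.placement import _down_pass, _leaf_masks_from_bundle, _query_masks

    cols = sorted(aligned.column_map)
    tree = bundle.tree
    leaf_masks = _leaf_masks_from_bundle(bundle, cols)
    q = _query_masks(aligned, query_seq, cols)
    out = {}
    for edge in [n for n in tree.preorder() if n != tree.root_id] + [ROOT_EDGE]:
        t = tree.copy()
        leaf = TreeNode("__q", None, [], 0.0)
        ind = TreeNode("__i", None, [], None)
        if edge == ROOT_EDGE:
            old = t.nodes[t.root_id]
            ind.children = [old.id, "__q"]
            old.parent = "__i"
            leaf.parent = "__i"
            t.nodes["__i"] = ind
            t.nodes["__q"] = leaf
            t.root_id = "__i"
        else:
            below = t.nodes[edge]
            par = t.nodes[below.parent]
            ind.parent = par.id
            ind.children = [edge, "__q"]
            par.children[par.children.index(edge)] = "__i"
            below.parent = "__i"
            leaf.parent = "__i"
            t.nodes["__i"] = ind
            t.nodes["__q"] = leaf
        lm = dict(leaf_masks)
        lm["__q"] = q
        _, costs = _down_pass(t, lm, len(cols))
        out[edge] = int(costs[t.root_id].sum())
    return out


class TestFitchCost:
    def test_constant_column_costs_zero(self):
        t = parse_newick("((A,B)X,(C,D)Y)R;")
        assert fitch_cost(t, {l: {"A"} for l in "ABCD"}) == 0

    def test_two_cherries_two_states(self):
        t = parse_newick("((A,B)X,(C,D)Y)R;")
        states = {"A": {"A"}, "B": {"A"}, "C": {"C"}, "D": {"C"}}
        assert fitch_cost(t, states) == 1
        assert fitch_cost(t, states) == enumerate_min_substitutions(t, states)

    def test_missing_leaf_raises(self):
        t = parse_newick("(A,B)R;")
        with pytest.raises(KeyError):
            fitch_cost(t, {"A": {"A"}})

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        """Hartigan downpass equals brute-force minimum over all internal
        assignments, on random trees <= 8 leaves with random state sets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        t = synth.simulate_tree(n, seed=seed)
        alphabet = "ACDE"
        states = {}
        for leaf in t.leaves():
            k = int(rng.integers(1, 3))
            states[leaf] = set(rng.choice(list(alphabet), size=k, replace=False))
        assert fitch_cost(t, states) == enumerate_min_substitutions(t, states)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_deviant_leaf_costs_one(self, seed):
        t = synth.simulate_tree(6, seed=seed)
        leaves = t.leaves()
        states = {l: {"A"} for l in leaves}
        states[leaves[int(np.random.default_rng(seed).integers(6))]] = {"W"}
        assert fitch_cost(t, states) == 1


class TestEdgePlacementCosts:
    @pytest.mark.parametrize("seed", range(20))
    def test_incremental_equals_naive_recomputation(self, seed):
        """Two-pass incremental costs exactly match per-edge augmented-tree
        Fitch on random simulated families (<= 12 leaves)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        bundle, _, _ = synth.simulate_family(n_leaves=n, seq_len=50, rate=0.8, seed=seed)
        prof = build_profile(bundle.msa)
        leaf = bundle.tree.leaves()[int(rng.integers(n))]
        q = bundle.msa.ungapped(leaf)
        al = score_and_align(q, prof)
        assert edge_placement_costs(bundle, al, q) == naive_augmented_costs(bundle, al, q)

    def test_identical_query_zero_delta_on_own_edge(self, small_bundle):
        bundle, _, _ = small_bundle
        prof = build_profile(bundle.msa)
        q = bundle.msa.ungapped("L7")
        al = score_and_align(q, prof)
        _, placement = graft(bundle, al, q)
        assert placement.delta_cost == 0
        assert "L7" in placement.tie_edges

    def test_all_missing_query_rejected(self, small_bundle):
        bundle, _, _ = small_bundle
        prof = build_profile(bundle.msa)
        q = "X" * 50
        al = score_and_align(q, prof)
        with pytest.raises(ValueError, match="uninformative query"):
            edge_placement_costs(bundle, al, q)


class TestGraft:
    def test_graft_adds_one_leaf_one_internal(self, small_bundle):
        bundle, _, _ = small_bundle
        prof = build_profile(bundle.msa)
        q = bundle.msa.ungapped("L2")
        al = score_and_align(q, prof)
        grafted, placement = graft(bundle, al, q)
        assert len(grafted.leaves()) == len(bundle.tree.leaves()) + 1
        assert len(grafted.nodes) == len(bundle.tree.nodes) + 2
        assert "ANGRAFTED" in grafted.nodes and "ANINDUCED" in grafted.nodes
        # removing both restores the original topology
        restored = grafted.remove_leaf("ANGRAFTED")
        assert set(restored.nodes) == set(bundle.tree.nodes)
        for nid in restored.nodes:
            assert restored.nodes[nid].children == bundle.tree.nodes[nid].children

    def test_induced_node_splits_branch_in_half(self, small_bundle):
        bundle, _, _ = small_bundle
        prof = build_profile(bundle.msa)
        q = bundle.msa.ungapped("L2")
        al = score_and_align(q, prof)
        grafted, placement = graft(bundle, al, q)
        if placement.edge != ROOT_EDGE:
            orig = bundle.tree.nodes[placement.edge].branch_length
            ind = grafted.nodes["ANINDUCED"]
            below = grafted.nodes[placement.edge]
            assert ind.branch_length == pytest.approx(orig / 2)
            assert below.branch_length == pytest.approx(orig / 2)
        assert grafted.nodes["ANGRAFTED"].branch_length == 0.0

    def test_tie_between_identical_sister_leaves_resolves_rootward(self):
        """Query equal to two identical sister leaves: the parent edge wins
        the tie, and the tie set is verified against brute-force costs."""
        tree = parse_newick("(((A:1,B:1)AN2:1,C:1)AN1:1,(D:1,E:1)AN3:1)AN0;")
        # A/B uniquely share K at column 2; every other leaf carries W there,
        # so the root's state set excludes K and the ROOT pseudo-edge cannot tie
        rows = {
            "A": "MKLVNPQRST",
            "B": "MKLVNPQRST",
            "C": "MWLVNPQRST",
            "D": "MWLVNPQRST",
            "E": "MWLVNPQRST",
        }
        msa = FamilyMSA("fam", rows)
        bundle = FamilyBundle(tree, msa, TermAnnotationMap([]), {})
        prof = build_profile(msa)
        q = rows["A"]
        al = score_and_align(q, prof)
        costs = edge_placement_costs(bundle, al, q)
        _, placement = graft(bundle, al, q)
        assert placement.edge == "AN2"
        assert {"A", "B", "AN2"} <= set(placement.tie_edges)
        min_cost = min(costs.values())
        assert set(placement.tie_edges) == {e for e, c in costs.items() if c == min_cost}

    @pytest.mark.parametrize("seed", range(8))
    def test_delta_zero_for_existing_leaf_sequences(self, seed):
        """delta_cost = 0 whenever the query equals an existing leaf
        restricted to match columns."""
        bundle, _, _ = synth.simulate_family(n_leaves=10, seq_len=60, rate=0.7, seed=seed)
        prof = build_profile(bundle.msa)
        for leaf in bundle.tree.leaves()[:3]:
            q = bundle.msa.ungapped(leaf)
            al = score_and_align(q, prof)
            _, placement = graft(bundle, al, q)
            assert placement.delta_cost == 0


class TestJplace:
    def test_document_structure_and_edge_numbering(self, small_bundle):
        bundle, _, _ = small_bundle
        prof = build_profile(bundle.msa)
        q = bundle.msa.ungapped("L4")
        al = score_and_align(q, prof, query_id="Q1")
        _, placement = graft(bundle, al, q)
        doc = export_jplace(placement, bundle.tree)
        assert doc["version"] == 3
        assert doc["fields"] == ["edge_num", "like", "delta_cost"]
        assert len(doc["placements"]) == 1
        rec = doc["placements"][0]
        assert rec["n"] == ["Q1"]
        assert len(rec["p"]) == len(placement.tie_edges)
        nums = [row[0] for row in rec["p"]]
        assert nums == sorted(nums)
        # every edge number in the doc appears in the tree string
        for num in nums:
            assert f"{{{num}}}" in doc["tree"]
        json.dumps(doc)  # serializable

    def test_tree_string_consistent_with_serialization(self, small_bundle):
        bundle, _, _ = small_bundle
        doc = export_jplace([], bundle.tree)
        import re

        stripped = re.sub(r"\{\d+\}", "", doc["tree"])
        from phylograft.reference_library import serialize_newick

        assert stripped == serialize_newick(bundle.tree)


class TestEdgeDistance:
    def test_same_and_adjacent(self):
        t = parse_newick("((A:1,B:1)AN1:1,C:1)AN0;")
        assert edge_topological_distance(t, "A", "A") == 0
        assert edge_topological_distance(t, "A", "B") == 1
        assert edge_topological_distance(t, "A", "AN1") == 1
        assert edge_topological_distance(t, "A", "C") == 2
        assert edge_topological_distance(t, ROOT_EDGE, "AN1") == 1
        assert edge_topological_distance(t, ROOT_EDGE, "A") == 2
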