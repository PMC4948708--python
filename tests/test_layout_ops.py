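import itertools

import pytest

from treeside import (
    LeafSetMismatchError,
    StructureError,
    Tree,
    ValidationError,
    VizState,
    best_rooting,
    collapse_at_depth,
    compare,
    estimate_collapse_depth,
    expand_path_to,
    highlight_subtree,
    leaf_order_distance,
    optimize_leaf_order,
    parse_newick,
    search_leaf,
    splits,
    visible_nodes,
)
from treeside.layout_ops import _best_rooting_naive, hidden_nodes
from treeside.fixtures import PerturbationPlan, balanced_tree, perturb, random_tree

from conftest import clade_sets, node_by_leafset


class TestBestRooting:
    def test_self_rooting_unchanged(self, quartet):
        other = parse_newick("((A,B),(C,D));")
        assert best_rooting(other, quartet) is quartet

    def test_recovers_reference_rooting(self, quartet, caterpillar):
        out = best_rooting(quartet, caterpillar)
        assert clade_sets(out) == clade_sets(quartet)
        assert compare(out, quartet).aggregate == 1.0

    def test_split_set_unchanged(self):
        ref = random_tree(20, 1)
        query = perturb(ref, PerturbationPlan(3, True, True, 77))
        out = best_rooting(ref, query)
        assert splits(out) == splits(query)

    @pytest.mark.parametrize("n", [8, 16, 64])
    def test_rerooted_copy_recovered(self, n):
        ref = random_tree(n, n)
        query = perturb(ref, PerturbationPlan(0, True, True, n + 1))
        out = best_rooting(ref, query)
        assert compare(out, ref).aggregate == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_shared_sweep_matches_naive_enumeration(self, seed):
        n = 5 + seed
        ref = random_tree(n, seed)
        query = perturb(ref, PerturbationPlan(seed % 3, True, True, seed + 500))
        fast = best_rooting(ref, query)
        naive = _best_rooting_naive(ref, query)
        assert compare(fast, ref).aggregate == pytest.approx(
            compare(naive, ref).aggregate, abs=1e-9
        )

    def test_polytomies_handled(self):
        ref = parse_newick("((A,B,C),(D,E));")
        query = parse_newick("(A,(B,(C,(D,E))));")
        out = best_rooting(ref, query)
        assert compare(out, ref).aggregate >= compare(query, ref).aggregate

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            best_rooting(parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));"))


class TestOptimizeLeafOrder:
    def test_reordered_quartet_recovered(self, quartet):
        query = parse_newick("((C,D),(B,A));")
        out = optimize_leaf_order(quartet, query)
        assert [l.label for l in out.leaves()] == ["A", "B", "C", "D"]
        assert leaf_order_distance(quartet, out) == 0

    def test_already_ordered_unchanged(self, quartet):
        other = parse_newick("((A,B),(C,D));")
        out = optimize_leaf_order(quartet, other)
        assert [l.label for l in out.leaves()] == [l.label for l in other.leaves()]

    def test_topology_unchanged(self):
        ref = random_tree(30, 2)
        query = perturb(ref, PerturbationPlan(2, True, True, 13))
        out = optimize_leaf_order(ref, query)
        assert splits(out) == splits(query)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_optimum_same_topology(self, seed):
        # brute force over every combination of child orders (n <= 8)
        ref = random_tree(8, seed)
        query = perturb(ref, PerturbationPlan(0, False, True, seed + 60))
        out = optimize_leaf_order(ref, query)
        heuristic = leaf_order_distance(ref, out)

        internals = [n for n in query.nodes() if not n.is_leaf]
        best = None
        for perms in itertools.product(
            *(itertools.permutations(range(len(n.children))) for n in internals)
        ):
            work = query.copy()
            w_internals = [n for n in work.nodes() if not n.is_leaf]
            for node, perm in zip(w_internals, perms):
                node.children = [node.children[i] for i in perm]
            work.rebuild()
            d = leaf_order_distance(ref, work)
            if best is None or d < best:
                best = d
        assert heuristic == best == 0

    def test_objective_never_increases(self):
        for seed in range(6):
            ref = random_tree(24, seed)
            query = perturb(ref, PerturbationPlan(4, True, True, seed + 90))
            before = leaf_order_distance(ref, query)
            after = leaf_order_distance(ref, optimize_leaf_order(ref, query))
            assert after <= before

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            optimize_leaf_order(parse_newick("(A,B);"), parse_newick("(A,C);"))


class TestIdentityRecovery:
    @pytest.mark.parametrize("n", [8, 32, 200])
    def test_end_to_end(self, n):
        ref = random_tree(n, n * 7, with_lengths=True)
        query = perturb(ref, PerturbationPlan(0, True, True, n * 7 + 1))
        out = optimize_leaf_order(ref, best_rooting(ref, query))
        assert compare(out, ref).aggregate == 1.0
        assert splits(out) == splits(ref)
        assert leaf_order_distance(ref, out) == 0


class TestCollapse:
    def test_small_tree_needs_no_collapsing(self, quartet):
        state = VizState(viewport=(800, 800), label_height_px=16)
        depth = estimate_collapse_depth(quartet, state)
        assert depth == 2  # the full depth of ((A,B),(C,D))
        assert collapse_at_depth(quartet, state, depth).collapsed == set()

    def test_balanced_1024_leaves_viewport_640(self):
        tree = balanced_tree(1024)
        state = VizState(viewport=(640, 640), label_height_px=16)
        # 2^5 = 32 stubs * 16px = 512 <= 640; 2^6 * 16 = 1024 > 640
        assert estimate_collapse_depth(tree, state) == 5

    def test_viewport_smaller_than_one_label_clamps_to_one(self):
        tree = balanced_tree(64)
        state = VizState(viewport=(100, 10), label_height_px=16)
        assert estimate_collapse_depth(tree, state) == 1

    def test_fitting_rule_satisfied(self):
        for seed, n in ((0, 64), (1, 128), (2, 200)):
            tree = random_tree(n, seed)
            state = VizState(viewport=(640, 480), label_height_px=14)
            d = estimate_collapse_depth(tree, state)
            rows = [
                node
                for node in visible_nodes(tree, collapse_at_depth(tree, state, d))
                if node.is_leaf or (not node.is_leaf and node in collapse_at_depth(tree, state, d).collapsed)
            ]
            assert len(rows) * state.label_height_px <= state.viewport[1] or d == 1

    def test_depth_beyond_height_collapses_nothing(self, quartet):
        assert collapse_at_depth(quartet, VizState(), 10).collapsed == set()

    def test_quartet_depth_one(self, quartet):
        state = collapse_at_depth(quartet, VizState(), 1)
        assert len(state.collapsed) == 2
        vis = visible_nodes(quartet, state)
        assert len(vis) == 3  # root + two stubs
        assert not any(n.is_leaf for n in vis)

    def test_visible_hidden_partition(self):
        for seed in range(5):
            tree = random_tree(50, seed)
            for d in (1, 2, 3, 5):
                state = collapse_at_depth(tree, VizState(), d)
                vis = visible_nodes(tree, state)
                hid = hidden_nodes(tree, state)
                assert len(vis) + len(hid) == len(tree.nodes())
                assert set(vis).isdisjoint(hid)

    def test_invalid_viewport_rejected(self, quartet):
        with pytest.raises(ValidationError):
            estimate_collapse_depth(quartet, VizState(viewport=(0, 100)))


class TestExpandPath:
    def test_visible_target_leaves_state_unchanged(self, quartet):
        state = VizState()
        out = expand_path_to(quartet, state, quartet.find_leaf("A"))
        assert out.collapsed == state.collapsed

    def test_exactly_the_collapsed_ancestors_expanded(self):
        tree = random_tree(64, 12)
        state = VizState(collapsed={n for n in tree.nodes() if not n.is_leaf})
        target = tree.leaves()[20]
        out = expand_path_to(tree, state, target)
        expanded = state.collapsed - out.collapsed
        ancestors = set(target.ancestors())
        assert expanded == {n for n in ancestors if n in state.collapsed}
        assert target in visible_nodes(tree, out)

    def test_other_collapsed_nodes_untouched(self):
        tree = random_tree(64, 12)
        state = VizState(collapsed={n for n in tree.nodes() if not n.is_leaf})
        target = tree.leaves()[5]
        out = expand_path_to(tree, state, target)
        ancestors = set(target.ancestors())
        assert out.collapsed == {n for n in state.collapsed if n not in ancestors}

    def test_foreign_target_rejected(self, quartet, quartet_alt):
        with pytest.raises(StructureError):
            expand_path_to(quartet, VizState(), quartet_alt.root)


class TestSearch:
    def test_path_to_c(self, quartet):
        path = search_leaf(quartet, "C")
        assert path[0] is quartet.root
        assert path[-1].label == "C"
        assert [frozenset(l.label for l in n.leaves()) for n in path] == [
            frozenset("ABCD"),
            frozenset("CD"),
            frozenset("C"),
        ]

    def test_absent_label_empty(self, quartet):
        assert search_leaf(quartet, "Z") == []

    def test_search_is_case_sensitive(self, quartet):
        assert search_leaf(quartet, "c") == []

    def test_every_leaf_found(self):
        tree = random_tree(40, 4)
        for leaf in tree.leaves():
            path = search_leaf(tree, leaf.label)
            assert path[0] is tree.root
            assert path[-1] is leaf


class TestHighlight:
    def test_counterpart_highlighted(self, quartet):
        other = parse_newick("((A,B),(C,D));")
        cmp = compare(quartet, other)
        node = node_by_leafset(quartet, "AB")
        s1, s2 = highlight_subtree(quartet, other, cmp, node, VizState(), VizState())
        assert set(node.preorder()) <= s1.highlighted
        expected = set(node_by_leafset(other, "AB").preorder())
        assert expected <= s2.highlighted

    def test_bcn_in_collapsed_subtree_becomes_visible(self):
        t1 = random_tree(32, 6)
        t2 = perturb(t1, PerturbationPlan(0, False, True, 3))
        cmp = compare(t1, t2)
        node = next(
            n for n in t1.nodes() if not n.is_leaf and n.parent is not None and n.parent.parent
        )
        state2 = VizState(collapsed={n for n in t2.nodes() if not n.is_leaf and n.parent})
        _, out2 = highlight_subtree(t1, t2, cmp, node, VizState(), state2)
        assert cmp.bcn[node] in visible_nodes(t2, out2)

    def test_leaf_highlight_maps_to_namesake(self, quartet):
        other = parse_newick("((A,B),(C,D));")
        cmp = compare(quartet, other)
        leaf = quartet.find_leaf("B")
        s1, s2 = highlight_subtree(quartet, other, cmp, leaf, VizState(), VizState())
        assert leaf in s1.highlighted
        assert other.find_leaf("B") in s2.highlighted

    def test_lazy_computation_when_not_covered(self, quartet):
        from treeside import bcn_fast

        other = parse_newick("((A,B),(C,D));")
        cmp = bcn_fast(quartet, other, restrict_to=[quartet.root])
        node = node_by_leafset(quartet, "CD")
        assert node not in cmp.scores
        highlight_subtree(quartet, other, cmp, node, VizState(), VizState())
        assert node in cmp.scores

    def test_foreign_node_rejected(self, quartet, quartet_alt):
        cmp = compare(quartet, parse_newick("((A,B),(C,D));"))
        with pytest.raises(StructureError):
            highlight_subtree(
                quartet, parse_newick("((A,B),(C,D));"), cmp, quartet_alt.root,
                VizState(), VizState(),
            )
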