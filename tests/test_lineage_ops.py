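"""Clones, cuts, relationships and view-state edits against brute-force
oracles."""

import numpy as np
import pytest

from cladeview.lineage_ops import (
    ViewState,
    clone,
    clones_at_division_depth,
    clones_at_time,
    collapse,
    descendant_summary,
    displayed_leaves,
    expand,
    export_clone,
    lineage_path,
    mrca,
    prune,
    relationship_levels,
    subset_branches,
    unprune,
)
from cladeview.tree_io import canonical_form, node_times, parse_json_tree, parse_newick
from cladeview.spatial_join import join
from cladeview.synthetic_fixtures import SimConfig, place_cells, simulate_lineage

from conftest import balanced_tree, random_tree, star_tree
import oracles


class TestClone:
    def test_root_clone_is_all_leaves(self, small_tree):
        assert clone(small_tree, small_tree.root.label) == {"A", "B", "C"}

    def test_leaf_clone_is_itself(self, small_tree):
        assert clone(small_tree, "A") == {"A"}

    def test_unknown_label(self, small_tree):
        with pytest.raises(KeyError):
            clone(small_tree, "nope")

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_independent_traversal(self, seed):
        tree = random_tree(seed)
        g = oracles.as_digraph(tree)
        for label in tree.labels:
            assert clone(tree, label) == oracles.leaves_below(g, label)


class TestDescendantSummary:
    def test_leaf_counts_itself(self, small_tree):
        cells = _cells_for(["A"])
        joined = join(small_tree, cells)
        assert descendant_summary(small_tree, "A", joined) == ("A", 1, 1)

    def test_unpositioned_clone(self, small_tree):
        joined = join(small_tree, _cells_for(["A"]))
        label, total, on_viewer = descendant_summary(small_tree, "B", joined)
        assert (total, on_viewer) == (1, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_partial_coverage_counts(self, seed):
        cfg = SimConfig(n_leaves=40, seed=seed)
        tree, _ = simulate_lineage(cfg)
        cells = place_cells(tree, cfg)
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(tree.leaf_labels, size=25, replace=False))
        joined = join(tree, _subset(cells, keep))
        g = oracles.as_digraph(tree)
        for label in tree.labels:
            _, total, on_viewer = descendant_summary(tree, label, joined)
            members = oracles.leaves_below(g, label)
            assert total == len(members)
            assert on_viewer == len(members & set(keep))
            assert on_viewer <= total


def _cells_for(labels):
    import pandas as pd
    from cladeview.spatial_join import CellTable
    frame = pd.DataFrame(
        {"x": 0.0, "y": 0.0, "z": 0.0},
        index=pd.Index(labels, name="cell"),
    )
    return CellTable(frame)


def _subset(cells, labels):
    from cladeview.spatial_join import CellTable
    return CellTable(cells.frame.loc[list(labels)])


class TestDepthCut:
    def test_complete_binary_k1(self):
        tree = balanced_tree(3)
        part = clones_at_division_depth(tree, 1)
        assert part.n_groups == 2
        assert all(len(m) == 4 for m in part.groups.values())

    def test_beyond_max_depth_gives_singletons(self, small_tree):
        part = clones_at_division_depth(small_tree, 99)
        assert part.groups == {"A": {"A"}, "B": {"B"}, "C": {"C"}}

    def test_negative_depth_rejected(self, small_tree):
        with pytest.raises(ValueError):
            clones_at_division_depth(small_tree, -1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bfs_oracle(self, seed):
        tree = random_tree(seed)
        g = oracles.as_digraph(tree)
        for k in range(0, tree.max_depth + 2):
            part = clones_at_division_depth(tree, k)
            assert part.groups == oracles.depth_cut_groups(g, tree.root.label, k)

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_cover_of_all_cells(self, seed):
        tree = random_tree(seed)
        for k in (0, 1, 2, tree.max_depth):
            part = clones_at_division_depth(tree, k)
            members = [m for g_ in part.groups.values() for m in g_]
            assert len(members) == len(set(members))
            assert set(members) == set(tree.leaf_labels)


class TestTimeCut:
    def test_time_zero_is_one_group(self, small_tree):
        part = clones_at_time(small_tree, 0.0)
        assert part.n_groups == 1
        assert set(part.groups) == {small_tree.root.label}

    def test_after_all_leaves_singletons(self, small_tree):
        part = clones_at_time(small_tree, 99.0)
        assert part.groups == {"A": {"A"}, "B": {"B"}, "C": {"C"}}

    def test_requires_branch_lengths(self):
        tree = parse_newick("(A,B);", "none")
        with pytest.raises(ValueError):
            clones_at_time(tree, 1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_edge_crossing_oracle(self, seed):
        mode = "relative" if seed % 2 else "absolute"
        tree = random_tree(seed, bl_mode=mode)
        g = oracles.as_digraph(tree)
        times = node_times(tree)
        tmax = max(times.values())
        rng = np.random.default_rng(seed)
        for t in [0.0, tmax / 3, tmax, tmax + 1] + list(rng.uniform(0, tmax, 4)):
            part = clones_at_time(tree, float(t))
            expected = oracles.time_cut_groups(g, tree.root.label, mode, float(t))
            assert part.groups == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_groups_partition_contemporaneous_cells(self, seed):
        tree = random_tree(seed, bl_mode="relative")
        times = node_times(tree)
        tmax = max(times.values())
        for t in np.linspace(0, tmax + 0.5, 7):
            part = clones_at_time(tree, float(t))
            members = [m for g_ in part.groups.values() for m in g_]
            assert len(members) == len(set(members))
            # at any positive time every terminal cell belongs to a clone
            assert set(members) == set(tree.leaf_labels)


class TestMrcaAndRelationships:
    def test_mrca_of_self(self, small_tree):
        assert mrca(small_tree, "A", "A") == "A"

    def test_mrca_of_siblings_is_parent(self, small_tree):
        assert mrca(small_tree, "A", "B") == "_n2"

    @pytest.mark.parametrize("seed", range(25))
    def test_mrca_matches_ancestor_intersection(self, seed):
        tree = random_tree(seed)
        g = oracles.as_digraph(tree)
        rng = np.random.default_rng(seed)
        labels = tree.labels
        for _ in range(15):
            a, b = rng.choice(labels, 2)
            assert mrca(tree, str(a), str(b)) == \
                oracles.mrca_oracle(g, tree.root.label, str(a), str(b))

    def test_levels_in_three_leaf_tree(self, small_tree):
        rel = relationship_levels(small_tree, "A")
        assert rel.level == {"A": 2, "B": 1, "C": 0}

    def test_focal_must_be_leaf(self, small_tree):
        with pytest.raises(ValueError):
            relationship_levels(small_tree, "_n2")

    @pytest.mark.parametrize("seed", range(25))
    def test_levels_match_quadratic_oracle(self, seed):
        tree = random_tree(seed)
        g = oracles.as_digraph(tree)
        rng = np.random.default_rng(seed)
        focal = str(rng.choice(tree.leaf_labels))
        rel = relationship_levels(tree, focal)
        assert rel.level == oracles.relationship_oracle(g, tree.root.label, focal)

    @pytest.mark.parametrize("seed", range(15))
    def test_nested_clone_property(self, seed):
        """Cells at level >= L are exactly the clone of the focal cell's
        depth-L ancestor."""
        tree = random_tree(seed)
        rng = np.random.default_rng(seed + 1)
        focal = str(rng.choice(tree.leaf_labels))
        rel = relationship_levels(tree, focal)
        path = lineage_path(tree, focal)
        for level, ancestor in enumerate(path):
            at_least = {c for c, lv in rel.level.items() if lv >= level}
            assert at_least == clone(tree, ancestor)


class TestLineagePath:
    def test_path_of_root(self, small_tree):
        assert lineage_path(small_tree, "_n1") == ["_n1"]

    def test_path_structure(self, small_tree):
        assert lineage_path(small_tree, "A") == ["_n1", "_n2", "A"]

    @pytest.mark.parametrize("seed", range(10))
    def test_length_is_depth_plus_one(self, seed):
        tree = random_tree(seed)
        for label in tree.leaf_labels:
            path = lineage_path(tree, label)
            assert len(path) == tree.depth(label) + 1
            assert path[0] == tree.root.label and path[-1] == label
            for parent, child in zip(path, path[1:]):
                assert tree.node(child).parent.label == parent


class TestViewState:
    def test_collapse_then_expand_is_identity(self, small_tree):
        view = ViewState()
        assert expand(small_tree, collapse(small_tree, view, "_n2"), "_n2") == view

    def test_collapse_is_idempotent(self, small_tree):
        view = collapse(small_tree, ViewState(), "_n2")
        assert collapse(small_tree, view, "_n2") == view

    def test_collapse_leaf_rejected(self, small_tree):
        with pytest.raises(ValueError):
            collapse(small_tree, ViewState(), "A")

    def test_prune_root_rejected(self, small_tree):
        with pytest.raises(ValueError):
            prune(small_tree, ViewState(), "_n1")

    def test_prune_leaf_removes_one_slot(self, small_tree):
        view = prune(small_tree, ViewState(), "A")
        assert displayed_leaves(small_tree, view) == ["B", "C"]

    def test_unprune_restores(self, small_tree):
        view = prune(small_tree, ViewState(), "A")
        assert unprune(small_tree, view, "A") == ViewState()

    @pytest.mark.parametrize("seed", range(15))
    def test_pruned_leaf_count_set_algebra(self, seed):
        tree = random_tree(seed)
        rng = np.random.default_rng(seed)
        internal = [n.label for n in tree.iter_nodes()
                    if n.children and n.parent is not None]
        if not internal:
            pytest.skip("tree too small for internal prune")
        target = str(rng.choice(internal))
        view = prune(tree, ViewState(), target)
        assert len(displayed_leaves(tree, view)) == \
            tree.n_leaves - len(clone(tree, target))

    def test_view_never_mutates_tree(self, small_tree):
        before = canonical_form(small_tree)
        view = collapse(small_tree, ViewState(), "_n2")
        prune(small_tree, view, "C")
        assert canonical_form(small_tree) == before

    def test_saved_selection_order_preserved(self, small_tree):
        view = ViewState().save_selection("first", {"A"})
        view = view.save_selection("second", {"B", "C"})
        assert [name for name, _ in view.saved_selections] == ["first", "second"]


class TestExportClone:
    def test_export_root_round_trips(self, small_tree):
        text = export_clone(small_tree, "_n1")
        again = parse_json_tree(text, "relative")
        assert canonical_form(again) == canonical_form(small_tree)

    def test_export_leaf_is_single_node(self, small_tree):
        sub = parse_json_tree(export_clone(small_tree, "C"), "relative")
        assert sub.n_nodes == 1 and sub.root.label == "C"

    @pytest.mark.parametrize("seed", range(15))
    def test_random_subtrees_round_trip(self, seed):
        tree = random_tree(seed)
        rng = np.random.default_rng(seed)
        label = str(rng.choice(tree.labels))
        sub = parse_json_tree(export_clone(tree, label), tree.bl_mode)
        assert set(sub.leaf_labels) == clone(tree, label)
        for node in sub.iter_nodes():
            orig = tree.node(node.label)
            if node.parent is not None:
                assert node.parent.label == orig.parent.label


class TestSubsetBranches:
    def test_resolved_tree_unchanged_however_large(self):
        # a fully resolved (binary) tree above the threshold
        tree, _ = simulate_lineage(SimConfig(n_leaves=1000, seed=3))
        display, report = subset_branches(tree, 500)
        assert display is tree
        assert not report.applicable and not report.applied

    def test_below_threshold_unchanged(self):
        tree = star_tree(400)
        display, report = subset_branches(tree, 500)
        assert display is tree
        assert report.applicable and not report.applied

    def test_star_capped_with_hidden_count(self):
        tree = star_tree(2000)
        display, report = subset_branches(tree, 500)
        assert display.n_leaves <= 500
        assert report.applied
        assert report.n_hidden_branches == 2000 - display.n_leaves == 1500

    def test_kept_children_are_label_sorted_prefix(self):
        tree = star_tree(10)
        display, report = subset_branches(tree, 4)
        kept = [c.label for c in display.root.children]
        assert kept == sorted(tree.leaf_labels)[:4]

    def test_floor_of_two_children_per_polytomy(self):
        # many nested polytomies: even k=2 may exceed the cap; the floor wins
        from cladeview.tree_io import Node, LineageTree
        root = Node("r")
        for i in range(5):
            mid = Node(f"m{i}")
            root.add_child(mid)
            for j in range(4):
                mid.add_child(Node(f"m{i}x{j}"))
        tree = LineageTree(root, "none")
        display, report = subset_branches(tree, 3)
        for node in display.iter_nodes():
            if node.children:
                assert len(node.children) >= 2

    def test_deterministic(self):
        tree = star_tree(800)
        a, _ = subset_branches(tree, 500)
        b, _ = subset_branches(tree, 500)
        assert canonical_form(a) == canonical_form(b)
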