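"""Shared fixtures and random-tree generation for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cladeview.tree_io import LineageTree, Node
from cladeview.synthetic_fixtures import SimConfig, simulate_lineage


def random_tree(seed: int, max_leaves: int = 60,
                bl_mode: str | None = None,
                polytomy_rate: float | None = None) -> LineageTree:
    """One random lineage tree per seed: size, branch-length mode and
    polytomy rate drawn from the seed unless pinned by the caller."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_leaves + 1))
    if polytomy_rate is None:
        polytomy_rate = float(rng.choice([0.0, 0.0, 0.15, 0.3]))
    if bl_mode is None:
        bl_mode = str(rng.choice(["none", "relative", "absolute"]))
    tree, _log = simulate_lineage(
        SimConfig(n_leaves=n, seed=seed, polytomy_rate=polytomy_rate)
    )
    if bl_mode == "none":
        return LineageTree(_strip(tree.root), "none")
    if bl_mode == "absolute":
        from cladeview.tree_io import convert_bl_mode
        return convert_bl_mode(tree, "absolute")
    return tree


def _strip(node: Node) -> Node:
    new = Node(node.label)
    for c in node.children:
        new.add_child(_strip(c))
    return new


def star_tree(n_leaves: int, bl_mode: str = "none") -> LineageTree:
    """A single polytomy with ``n_leaves`` children."""
    root = Node("root")
    for i in range(n_leaves):
        bl = 1.0 if bl_mode != "none" else None
        root.add_child(Node(f"L{i:04d}", branch_length=bl))
    if bl_mode != "none":
        root.branch_length = 0.0
    return LineageTree(root, bl_mode)


def balanced_tree(depth: int, bl_mode: str = "none") -> LineageTree:
    """Complete binary tree; leaves are at depth ``depth``."""
    counter = [0]

    def build(d: int) -> Node:
        counter[0] += 1
        bl = None if bl_mode == "none" else 1.0
        node = Node(f"n{counter[0]}", branch_length=bl)
        if d > 0:
            node.add_child(build(d - 1))
            node.add_child(build(d - 1))
        return node

    root = build(depth)
    if bl_mode == "relative":
        root.branch_length = 0.0
    elif bl_mode == "absolute":
        _make_absolute(root, 0.0)
    return LineageTree(root, bl_mode)


def _make_absolute(node: Node, t: float) -> None:
    node.branch_length = t
    for c in node.children:
        _make_absolute(c, t + 1.0)


@pytest.fixture
def small_tree() -> LineageTree:
    """((A,B),C) with relative lengths 1,2 / 1 and 3."""
    from cladeview.tree_io import parse_newick
    return parse_newick("((A:1,B:2):1,C:3);", "relative")


@pytest.fixture
def eight_leaf_tree() -> LineageTree:
    return balanced_tree(3)
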