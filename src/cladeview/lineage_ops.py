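"""Tree computations behind the interactive lineage-browsing features.

Conventions used throughout (documented in docs/methods.md):

* the root has depth 0 and "number of divisions" means edge count from the
  root, so a division-depth cut at ``k=0`` returns the root's clone;
* a clone is the leaf set of a subtree, and a leaf's clone is itself, so a
  leaf's ``total_descendants`` is 1 and hover counts equal clone sizes;
* a time cut treats an edge ``p → c`` as alive at time ``t`` iff
  ``time(p) < t ≤ time(c)`` (the root's incoming edge extends back to
  ``-inf``), and a terminated leaf stays alive at all later times — cells
  that stopped dividing persist to the final time point.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

from .tree_io import LineageTree, Node, node_times, to_json, _copy_subtree


@dataclass
class ClonePartition:
    """Assignment of cells to clones induced by a depth cut, a time cut, or
    an explicit ancestor set. ``groups`` maps founder label → member cells."""

    cut_kind: str  # "ancestors" | "division_depth" | "time"
    cut_value: float | int | None
    groups: dict[str, set[str]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict[str, str]:
        """Invert to a cell → founder map."""
        out: dict[str, str] = {}
        for founder, members in self.groups.items():
            for cell in members:
                out[cell] = founder
        return out

    def to_csv(self) -> str:
        lines = ["cell,group"]
        for founder in self.groups:
            for cell in sorted(self.groups[founder]):
                lines.append(f"{cell},{founder}")
        return "\n".join(lines) + "\n"


@dataclass
class RelationshipMap:
    """Degree of lineage relationship of every cell to one focal cell,
    quantified as the depth of their most recent common ancestor. Cells at
    level ≥ L are exactly the clone of the focal cell's depth-L ancestor —
    the nested-clone property."""

    focal: str
    level: dict[str, int]

    def to_csv(self) -> str:
        lines = ["cell,level"]
        for cell in sorted(self.level):
            lines.append(f"{cell},{self.level[cell]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ViewState:
    """Display overlay on a tree: collapsed and pruned branches plus named
    saved selections. Never mutates the underlying LineageTree."""

    collapsed: frozenset[str] = frozenset()
    pruned: frozenset[str] = frozenset()
    saved_selections: tuple[tuple[str, frozenset[str]], ...] = ()

    def save_selection(self, name: str, members: set[str]) -> "ViewState":
        return replace(
            self,
            saved_selections=self.saved_selections + ((name, frozenset(members)),),
        )


# ---------------------------------------------------------------------------
# Clones and summaries
# ---------------------------------------------------------------------------

def clone(tree: LineageTree, ancestor: str) -> set[str]:
    """All leaf labels in the subtree rooted at ``ancestor``; a leaf's clone
    is the leaf itself."""
    node = tree.node(ancestor)
    out: set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.add(n.label)
        else:
            stack.extend(n.children)
    return out


def descendant_summary(tree: LineageTree, label: str, joined=None) -> tuple[str, int, int]:
    """Hover summary for one node: (label, total descendants, descendants
    with 3D positions). ``joined`` is a JoinedDataset or any object with a
    ``matched`` label set; ``None`` means no cell is positioned."""
    members = clone(tree, label)
    positioned = joined.matched if joined is not None else set()
    return (label, len(members), len(members & positioned))


def clones_at_division_depth(tree: LineageTree, k: int) -> ClonePartition:
    """Partition cells into the clones founded after exactly ``k`` divisions.

    Founders are every node at edge-depth ``k`` plus every leaf shallower
    than ``k`` (a cell that stopped dividing early persists as a singleton).
    """
    if k < 0:
        raise ValueError(f"division depth must be >= 0, got {k}")
    groups: dict[str, set[str]] = {}
    for node in tree.iter_nodes():
        d = tree.depth(node.label)
        if d == k or (node.is_leaf and d < k):
            groups[node.label] = clone(tree, node.label)
    return ClonePartition("division_depth", k, groups)


def clones_at_time(tree: LineageTree, t: float) -> ClonePartition:
    """Partition cells into the clones existing at developmental time ``t``.

    An edge ``p → c`` is alive at ``t`` iff ``time(p) < t ≤ time(c)``; each
    alive edge founds the group ``clone(c)``. The root's incoming edge
    extends back indefinitely, so at ``t = 0`` the whole tree is one clone.
    Leaves with ``time(leaf) < t`` found singleton groups.
    """
    if tree.bl_mode == "none":
        raise ValueError("time cuts require branch lengths (bl_mode is 'none')")
    times = node_times(tree)
    groups: dict[str, set[str]] = {}
    for node in tree.iter_nodes():
        t_node = times[node.label]
        t_parent = times[node.parent.label] if node.parent else float("-inf")
        if t_parent < t <= t_node:
            groups[node.label] = clone(tree, node.label)
        elif node.is_leaf and t_node < t:
            groups[node.label] = {node.label}
    return ClonePartition("time", t, groups)


# ---------------------------------------------------------------------------
# Relationships
# ---------------------------------------------------------------------------

def _root_path(tree: LineageTree, label: str) -> list[Node]:
    node = tree.node(label)
    path = [node]
    while node.parent is not None:
        node = node.parent
        path.append(node)
    return path[::-1]


def mrca(tree: LineageTree, a: str, b: str) -> str:
    """Most recent common ancestor of two nodes (a node is its own ancestor)."""
    pa, pb = _root_path(tree, a), _root_path(tree, b)
    last = pa[0]
    for x, y in zip(pa, pb):
        if x is not y:
            break
        last = x
    return last.label


def relationship_levels(tree: LineageTree, focal: str) -> RelationshipMap:
    """Lineage relatedness of every cell to ``focal``: level(x) is the depth
    of MRCA(focal, x), from 0 (related only through the root) up to
    depth(focal) for the focal cell itself."""
    node = tree.node(focal)
    if not node.is_leaf:
        raise ValueError(f"focal cell {focal!r} is not a leaf")
    # walk the focal root path once; every cell's level is the depth of the
    # deepest focal ancestor whose subtree contains it
    level: dict[str, int] = {}
    for depth, anc in enumerate(_root_path(tree, focal)):
        for cell in clone(tree, anc.label):
            level[cell] = depth
    return RelationshipMap(focal, level)


def lineage_path(tree: LineageTree, cell: str) -> list[str]:
    """Ordered labels from the root down to ``cell``."""
    return [n.label for n in _root_path(tree, cell)]


# ---------------------------------------------------------------------------
# View-state edits (overlay only; the tree is never mutated)
# ---------------------------------------------------------------------------

def collapse(tree: LineageTree, view: ViewState, label: str) -> ViewState:
    """Mark an internal node collapsed: its subtree renders as one marker
    carrying the clone size. Idempotent."""
    node = tree.node(label)
    if node.is_leaf:
        raise ValueError(f"cannot collapse leaf {label!r}")
    return replace(view, collapsed=view.collapsed | {label})


def expand(tree: LineageTree, view: ViewState, label: str) -> ViewState:
    """Undo a collapse. Idempotent; expand∘collapse is the identity."""
    tree.node(label)
    return replace(view, collapsed=view.collapsed - {label})


def prune(tree: LineageTree, view: ViewState, label: str) -> ViewState:
    """Exclude a subtree from the displayed tree (layout and displayed-tree
    cuts); the underlying data is untouched."""
    node = tree.node(label)
    if node.parent is None:
        raise ValueError("cannot prune the root")
    return replace(view, pruned=view.pruned | {label})


def unprune(tree: LineageTree, view: ViewState, label: str) -> ViewState:
    tree.node(label)
    return replace(view, pruned=view.pruned - {label})


def displayed_leaves(tree: LineageTree, view: ViewState) -> list[str]:
    """Leaf slots of the displayed tree: pruned subtrees absent, each
    collapsed subtree contributing its root as a single slot."""
    out: list[str] = []

    def walk(node: Node) -> None:
        if node.label in view.pruned:
            return
        if node.is_leaf or node.label in view.collapsed:
            out.append(node.label)
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


# ---------------------------------------------------------------------------
# Clone export and branch subsetting
# ---------------------------------------------------------------------------

def export_clone(tree: LineageTree, label: str) -> str:
    """Serialize the subtree rooted at ``label`` as lineage JSON, lengths
    preserved, for downstream analysis."""
    node = tree.node(label)
    sub = _copy_subtree(node)
    if tree.bl_mode == "relative" and node.parent is not None:
        sub.branch_length = 0.0  # the exported root starts its own clock
    subtree = LineageTree(sub, tree.bl_mode)
    return to_json(subtree)


def subtree_as_tree(tree: LineageTree, label: str) -> LineageTree:
    """The clone rooted at ``label`` as a standalone LineageTree."""
    node = tree.node(label)
    sub = _copy_subtree(node)
    if tree.bl_mode == "relative" and node.parent is not None:
        sub.branch_length = 0.0
    return LineageTree(sub, tree.bl_mode)


@dataclass
class SubsetReport:
    """What branch subsetting did: inapplicable, unnecessary, or per-polytomy
    hidden-branch counts."""

    applicable: bool
    applied: bool
    reason: str
    hidden_per_polytomy: dict[str, int] = field(default_factory=dict)

    @property
    def n_hidden_branches(self) -> int:
        return sum(self.hidden_per_polytomy.values())


def subset_branches(
    tree: LineageTree, max_cells: int = 500
) -> tuple[LineageTree, SubsetReport]:
    """Reduce an unresolved tree for display by keeping only the first ``k``
    label-sorted children at every polytomy.

    Activated only when the tree holds more than ``max_cells`` cells *and*
    is not completely resolved (has polytomies) — a fully resolved tree is
    returned unchanged however large. ``k`` is the largest uniform per-
    polytomy child count that brings the displayed leaf count to at most
    ``max_cells``, floored at 2 children per polytomy.
    """
    if max_cells < 1:
        raise ValueError(f"max_cells must be >= 1, got {max_cells}")
    if not tree.has_polytomies:
        return tree, SubsetReport(
            False, False, "not applicable: tree is completely resolved"
        )
    if tree.n_leaves <= max_cells:
        return tree, SubsetReport(
            True, False,
            f"not needed: {tree.n_leaves} cells <= threshold {max_cells}",
        )

    def leaves_keeping(k: int) -> int:
        def count(node: Node) -> int:
            if node.is_leaf:
                return 1
            kids = node.children
            if len(kids) >= 3:
                kids = sorted(kids, key=lambda c: c.label)[:max(k, 2)]
            return sum(count(c) for c in kids)
        return count(tree.root)

    max_arity = max(len(n.children) for n in tree.iter_nodes() if n.children)
    k = max_arity
    while k > 2 and leaves_keeping(k) > max_cells:
        k -= 1

    hidden: dict[str, int] = {}

    def build(node: Node) -> Node:
        new = Node(node.label, branch_length=node.branch_length)
        kids = node.children
        if len(kids) >= 3:
            kept = sorted(kids, key=lambda c: c.label)[:max(k, 2)]
            n_hidden = len(kids) - len(kept)
            if n_hidden:
                hidden[node.label] = n_hidden
            kids = kept
        for c in kids:
            new.add_child(build(c))
        return new

    display = LineageTree(build(tree.root), tree.bl_mode)
    report = SubsetReport(
        True, True,
        f"kept first {max(k, 2)} label-sorted children per polytomy "
        f"({display.n_leaves} of {tree.n_leaves} cells displayed)",
        hidden,
    )
    return display, report
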