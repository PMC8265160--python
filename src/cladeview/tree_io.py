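"""Parsing, validation and serialization of cell-lineage trees.

Two on-disk formats are accepted:

* **Newick** — standard dialect: single-quoted labels (with ``''`` escaping),
  square-bracket comments stripped, whitespace outside quotes ignored.
* **Hierarchical JSON** — each node is an object with a ``"name"`` key, an
  optional ``"children"`` list and an optional ``"length"`` number. Unknown
  keys are ignored with a warning.

Branch lengths may encode division timing in one of two conventions:
``relative`` lengths are parent→child distances, ``absolute`` lengths are
each node's cumulative distance from the root (and must therefore be
non-decreasing toward the leaves). ``bl_mode="none"`` declares a pure
topology; any lengths present in the file are then discarded with a warning.

Cell labels are the join key between the lineage view and the 3D view, so
duplicate labels are a hard error and unlabeled nodes are auto-named
deterministically (``_n<k>``, breadth-first from the root).
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional

BL_MODES = ("none", "relative", "absolute")

# Characters that force quoting of a label in Newick output.
_NEWICK_SPECIALS = set("()[]{}/\\,;:=*'\"`+<> \t\n")


class TreeFormatError(ValueError):
    """Input is not recognizably Newick or lineage JSON."""


class TreeParseError(TreeFormatError):
    """Structurally invalid tree text; carries a character position when known."""

    def __init__(self, message: str, pos: Optional[int] = None):
        self.pos = pos
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)


@dataclass(eq=False)
class Node:
    """One cell in the lineage: a leaf is a terminal cell, an internal node
    a dividing ancestor. ``branch_length`` is interpreted per the owning
    tree's ``bl_mode``."""

    label: str
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    branch_length: Optional[float] = None
    # source position, for error messages; not part of the data model
    _pos: Optional[int] = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_polytomy(self) -> bool:
        return len(self.children) >= 3

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class LineageTree:
    """A rooted tree of uniquely labeled cells with optional branch lengths.

    Construction validates the invariants: a single root, unique labels,
    branch lengths consistent with ``bl_mode`` (all ``None`` when mode is
    ``"none"``; non-negative; non-decreasing root→leaf in absolute mode).
    """

    def __init__(self, root: Node, bl_mode: str = "none"):
        if bl_mode not in BL_MODES:
            raise ValueError(f"bl_mode must be one of {BL_MODES}, got {bl_mode!r}")
        self.root = root
        self.bl_mode = bl_mode
        self._index: dict[str, Node] = {}
        self._depths: Optional[dict[str, int]] = None
        self._autoname()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _autoname(self) -> None:
        """Assign deterministic labels ``_n<k>`` (breadth-first) to unnamed nodes."""
        taken = {n.label for n in self._bfs() if n.label}
        k = 1
        for node in self._bfs():
            if not node.label:
                while f"_n{k}" in taken:
                    k += 1
                node.label = f"_n{k}"
                taken.add(node.label)
                k += 1

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise TreeParseError("root must have no parent")
        for node in self._bfs():
            if node.label in self._index:
                raise TreeParseError(
                    f"duplicate label {node.label!r}", node._pos
                )
            self._index[node.label] = node
            for c in node.children:
                if c.parent is not node:
                    raise TreeParseError(
                        f"inconsistent parent link at {c.label!r}"
                    )
            bl = node.branch_length
            if self.bl_mode == "none":
                if bl is not None:
                    raise TreeParseError(
                        f"branch length on {node.label!r} but bl_mode is 'none'"
                    )
            else:
                if bl is None:
                    if node is self.root:
                        node.branch_length = 0.0
                    else:
                        raise TreeParseError(
                            f"missing branch length on {node.label!r} "
                            f"(bl_mode={self.bl_mode!r})", node._pos
                        )
                elif not math.isfinite(bl) or bl < 0:
                    raise TreeParseError(
                        f"branch length on {node.label!r} must be a finite "
                        f"non-negative number, got {bl!r}", node._pos
                    )
        if self.bl_mode == "absolute":
            for node in self._bfs():
                for c in node.children:
                    if c.branch_length < node.branch_length - 1e-12:
                        raise TreeParseError(
                            f"absolute branch lengths decrease from "
                            f"{node.label!r} ({node.branch_length}) to "
                            f"{c.label!r} ({c.branch_length})", c._pos
                        )

    # -- traversal ------------------------------------------------------------

    def _bfs(self) -> Iterator[Node]:
        queue = deque([self.root])
        while queue:
            node = queue.popleft()
            yield node
            queue.extend(node.children)

    def iter_nodes(self) -> Iterator[Node]:
        """Breadth-first iteration from the root."""
        return self._bfs()

    def iter_leaves(self) -> Iterator[Node]:
        for node in self._bfs():
            if node.is_leaf:
                yield node

    # -- queries --------------------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def node(self, label: str) -> Node:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    @property
    def labels(self) -> list[str]:
        return list(self._index)

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.iter_leaves()]

    @property
    def n_nodes(self) -> int:
        return len(self._index)

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    @property
    def has_polytomies(self) -> bool:
        return any(n.is_polytomy for n in self._bfs())

    def depth(self, label: str) -> int:
        """Number of divisions (edges) from the root to this node."""
        if self._depths is None:
            self._depths = {}
            for node in self._bfs():
                p = node.parent
                self._depths[node.label] = 0 if p is None else self._depths[p.label] + 1
        if label not in self._depths:
            self.node(label)  # raise the standard lookup error
        return self._depths[label]

    @property
    def max_depth(self) -> int:
        return max(self.depth(n.label) for n in self.iter_leaves())

    def copy(self) -> "LineageTree":
        return LineageTree(_copy_subtree(self.root), self.bl_mode)


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, branch_length=node.branch_length)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


# ---------------------------------------------------------------------------
# Format detection and reports
# ---------------------------------------------------------------------------

@dataclass
class FormatReport:
    """Outcome of validating one lineage-tree file."""

    format: str
    parse_ok: bool
    messages: list[tuple[str, str]] = field(default_factory=list)
    n_cells: int = 0
    n_nodes: int = 0
    has_branch_lengths: bool = False
    has_polytomies: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": self.format,
                "parse_ok": self.parse_ok,
                "messages": [list(m) for m in self.messages],
                "n_cells": self.n_cells,
                "n_nodes": self.n_nodes,
                "has_branch_lengths": self.has_branch_lengths,
                "has_polytomies": self.has_polytomies,
            },
            indent=2,
        )


def detect_tree_format(text: str) -> str:
    """Identify a lineage-tree file as ``"newick"`` or ``"json"``.

    JSON wins when the content parses as a JSON object or array; Newick is
    recognized by an opening ``(`` or bare label and a terminal ``;``.
    """
    if not text or not text.strip():
        raise TreeFormatError("empty tree file")
    stripped = text.lstrip()
    if stripped[0] in "{[":
        try:
            value = json.loads(stripped)
        except json.JSONDecodeError as exc:
            raise TreeFormatError(
                f"content starts like JSON but does not parse ({exc}); "
                "nor is it Newick (must end with ';')"
            ) from None
        if isinstance(value, (dict, list)):
            return "json"
    if stripped.rstrip().endswith(";"):
        return "newick"
    raise TreeFormatError(
        "unrecognized tree format: not a JSON object/array and not a "
        "';'-terminated Newick string"
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

class _NewickScanner:
    """Minimal cursor over Newick text: strips [comments], skips whitespace
    outside quotes, reads quoted/bare labels and numeric lengths."""

    def __init__(self, text: str):
        self.text = text
        self.i = 0
        self.n = len(text)

    def _skip(self) -> None:
        while self.i < self.n:
            ch = self.text[self.i]
            if ch.isspace():
                self.i += 1
            elif ch == "[":  # comment — skip to matching bracket
                end = self.text.find("]", self.i + 1)
                if end == -1:
                    raise TreeParseError("unterminated [comment]", self.i)
                self.i = end + 1
            else:
                return

    def peek(self) -> str:
        self._skip()
        return self.text[self.i] if self.i < self.n else ""

    def take(self, ch: str) -> None:
        if self.peek() != ch:
            raise TreeParseError(f"expected {ch!r}", self.i)
        self.i += 1

    def label(self) -> str:
        self._skip()
        if self.i < self.n and self.text[self.i] == "'":
            return self._quoted()
        start = self.i
        while self.i < self.n and self.text[self.i] not in "()[],;:" \
                and not self.text[self.i].isspace():
            self.i += 1
        return self.text[start:self.i]

    def _quoted(self) -> str:
        self.i += 1
        out = []
        while self.i < self.n:
            ch = self.text[self.i]
            if ch == "'":
                if self.i + 1 < self.n and self.text[self.i + 1] == "'":
                    out.append("'")
                    self.i += 2
                    continue
                self.i += 1
                return "".join(out)
            out.append(ch)
            self.i += 1
        raise TreeParseError("unterminated quoted label", self.i)

    def length(self) -> float:
        self._skip()
        start = self.i
        while self.i < self.n and (self.text[self.i] in "+-.eE" or self.text[self.i].isdigit()):
            self.i += 1
        token = self.text[start:self.i]
        try:
            return float(token)
        except ValueError:
            raise TreeParseError(f"invalid branch length {token!r}", start) from None


def _parse_newick_raw(text: str) -> tuple[Node, bool]:
    """Parse Newick into a raw node structure; returns (root, saw_lengths)."""
    sc = _NewickScanner(text)
    saw_lengths = False

    def parse_clade() -> Node:
        nonlocal saw_lengths
        node = Node("", _pos=sc.i)
        if sc.peek() == "(":
            sc.take("(")
            while True:
                node.add_child(parse_clade())
                ch = sc.peek()
                if ch == ",":
                    sc.take(",")
                elif ch == ")":
                    sc.take(")")
                    break
                elif ch == "":
                    raise TreeParseError("unbalanced parentheses", sc.i)
                else:
                    raise TreeParseError(f"unexpected character {ch!r}", sc.i)
        node.label = sc.label()
        if sc.peek() == ":":
            sc.take(":")
            node.branch_length = sc.length()
            saw_lengths = True
        return node

    root = parse_clade()
    if sc.peek() != ";":
        raise TreeParseError("expected ';' at end of Newick", sc.i)
    sc.take(";")
    if sc.peek() != "":
        raise TreeParseError("trailing content after ';'", sc.i)
    return root, saw_lengths


def parse_newick(
    text: str,
    bl_mode: str = "none",
    messages: Optional[list[tuple[str, str]]] = None,
) -> LineageTree:
    """Parse a Newick string under a declared branch-length convention.

    When the file carries colon-lengths but ``bl_mode="none"``, lengths are
    discarded and a warning is appended to ``messages`` (if given).
    """
    root, saw_lengths = _parse_newick_raw(text)
    if bl_mode == "none" and saw_lengths:
        for n in _iter_raw(root):
            n.branch_length = None
        if messages is not None:
            messages.append(
                ("warning", "file contains branch lengths but bl_mode is "
                            "'none'; lengths discarded")
            )
    return LineageTree(root, bl_mode)


def _iter_raw(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _format_label_newick(label: str) -> str:
    if not label or any(ch in _NEWICK_SPECIALS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(bl: float) -> str:
    if bl == int(bl) and abs(bl) < 1e15:
        return str(int(bl))
    return repr(bl)


def to_newick(tree: LineageTree) -> str:
    """Serialize to Newick; lengths written iff the tree has a bl mode."""
    with_lengths = tree.bl_mode != "none"

    def fmt(node: Node) -> str:
        s = ""
        if node.children:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
        s += _format_label_newick(node.label)
        if with_lengths and node.branch_length is not None:
            s += ":" + _format_length(node.branch_length)
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Hierarchical JSON
# ---------------------------------------------------------------------------

_JSON_KEYS = {"name", "children", "length"}


def parse_json_tree(
    text: str,
    bl_mode: str = "none",
    messages: Optional[list[tuple[str, str]]] = None,
) -> LineageTree:
    """Parse the hierarchical JSON lineage schema.

    Every node object must carry ``"name"``; ``"children"`` (list) and
    ``"length"`` (number) are optional; other keys are ignored with a warning.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TreeParseError(f"invalid JSON: {exc.msg}", exc.pos) from None
    if isinstance(data, list):
        if len(data) != 1:
            raise TreeParseError(
                f"expected a single root object, got a list of {len(data)}"
            )
        data = data[0]
    saw_lengths = False
    warned_keys: set[str] = set()

    def build(obj: object) -> Node:
        nonlocal saw_lengths
        if not isinstance(obj, dict):
            raise TreeParseError(f"tree node must be an object, got {type(obj).__name__}")
        if "name" not in obj:
            raise TreeParseError(f"tree node missing 'name': keys {sorted(obj)}")
        extra = set(obj) - _JSON_KEYS
        if extra and messages is not None:
            for key in sorted(extra - warned_keys):
                messages.append(("warning", f"ignoring unknown key {key!r}"))
                warned_keys.add(key)
        node = Node(str(obj["name"]))
        if "length" in obj and obj["length"] is not None:
            node.branch_length = float(obj["length"])
            saw_lengths = True
        children = obj.get("children")
        if children is not None:
            if not isinstance(children, list):
                raise TreeParseError(
                    f"'children' of {node.label!r} must be a list"
                )
            for child in children:
                node.add_child(build(child))
        return node

    root = build(data)
    if bl_mode == "none" and saw_lengths:
        for n in _iter_raw(root):
            n.branch_length = None
        if messages is not None:
            messages.append(
                ("warning", "file contains branch lengths but bl_mode is "
                            "'none'; lengths discarded")
            )
    return LineageTree(root, bl_mode)


def to_json(tree: LineageTree, indent: Optional[int] = None) -> str:
    """Serialize to the hierarchical JSON schema (keys name/children/length)."""
    with_lengths = tree.bl_mode != "none"

    def encode(node: Node) -> dict:
        obj: dict = {"name": node.label}
        if with_lengths and node.branch_length is not None:
            obj["length"] = node.branch_length
        if node.children:
            obj["children"] = [encode(c) for c in node.children]
        return obj

    return json.dumps(encode(tree.root), indent=indent)


def parse_tree(
    text: str,
    bl_mode: str = "none",
    messages: Optional[list[tuple[str, str]]] = None,
) -> LineageTree:
    """Auto-detect the format and parse."""
    fmt = detect_tree_format(text)
    if fmt == "newick":
        return parse_newick(text, bl_mode, messages)
    return parse_json_tree(text, bl_mode, messages)


def format_report(text: str, bl_mode: str = "none") -> FormatReport:
    """Validate a tree file and summarize it without raising."""
    messages: list[tuple[str, str]] = []
    try:
        fmt = detect_tree_format(text)
    except TreeFormatError as exc:
        return FormatReport("unknown", False, [("error", str(exc))])
    try:
        tree = parse_tree(text, bl_mode, messages)
    except TreeFormatError as exc:
        messages.append(("error", str(exc)))
        return FormatReport(fmt, False, messages)
    return FormatReport(
        format=fmt,
        parse_ok=True,
        messages=messages,
        n_cells=tree.n_leaves,
        n_nodes=tree.n_nodes,
        has_branch_lengths=tree.bl_mode != "none",
        has_polytomies=tree.has_polytomies,
    )


# ---------------------------------------------------------------------------
# Branch-length semantics
# ---------------------------------------------------------------------------

def node_times(tree: LineageTree) -> dict[str, float]:
    """Time of each node measured from the root.

    Absolute mode: the stored length *is* the time. Relative mode: the sum
    of the lengths on the root→node path, including the root's own length
    (the founder cell's lifespan before its first division; 0 when absent).
    Times are non-decreasing along every root→leaf path.
    """
    if tree.bl_mode == "none":
        raise ValueError("node_times requires branch lengths (bl_mode is 'none')")
    times: dict[str, float] = {}
    for node in tree.iter_nodes():
        if tree.bl_mode == "absolute":
            times[node.label] = float(node.branch_length)
        else:
            parent_t = 0.0 if node.parent is None else times[node.parent.label]
            times[node.label] = parent_t + float(node.branch_length)
    return times


def convert_bl_mode(tree: LineageTree, target: str) -> LineageTree:
    """Convert between relative and absolute branch-length conventions.

    Node times are invariant under conversion; converting twice recovers the
    original lengths to within 1e-9.
    """
    if target not in ("relative", "absolute"):
        raise ValueError(f"target must be 'relative' or 'absolute', got {target!r}")
    if tree.bl_mode == "none":
        raise ValueError("cannot convert a tree without branch lengths")
    times = node_times(tree)

    def build(node: Node) -> Node:
        if target == "absolute":
            bl = times[node.label]
        else:
            bl = times[node.label] - (times[node.parent.label] if node.parent else 0.0)
        new = Node(node.label, branch_length=bl)
        for c in node.children:
            new.add_child(build(c))
        return new

    return LineageTree(build(tree.root), target)


# ---------------------------------------------------------------------------
# Canonical form (isomorphism checks)
# ---------------------------------------------------------------------------

def canonical_form(tree: LineageTree, with_lengths: bool = True) -> str:
    """A Newick-like string invariant under child reordering.

    Two trees are label-isomorphic (same labels, same parent map, same
    lengths) iff their canonical forms are equal.
    """
    use_bl = with_lengths and tree.bl_mode != "none"

    def fmt(node: Node) -> str:
        s = ""
        if node.children:
            s = "(" + ",".join(sorted(fmt(c) for c in node.children)) + ")"
        s += _format_label_newick(node.label)
        if use_bl and node.branch_length is not None:
            s += f":{node.branch_length:.9g}"
        return s

    return fmt(tree.root) + ";"
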