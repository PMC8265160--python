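"""CSV side-files (coordinates, annotations, expression, saved selections),
label joins between the tree and the 3D cells, and MaMuT tracking-XML import.

All CSV dialects are comma-separated UTF-8 with a mandatory header matched
case-insensitively after trimming:

* coordinates — ``cell,X,Y,Z``, one row per positioned cell;
* annotations / saved selections — ``cell,annotation``, one category per cell;
* expression — first column ``cell``, remaining columns gene names, values
  non-negative reals (cells as rows, genes as columns).

The cell label is the only join key between the lineage tree and the 3D
view; partial coverage (a tree larger than the coordinate set, or vice
versa) is legal and bookkept, an empty intersection is an error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

from .tree_io import LineageTree, Node


class TableFormatError(ValueError):
    """A CSV side-file violates its declared layout."""


class JoinError(ValueError):
    """Tree and coordinates share no cell labels."""


class MamutError(ValueError):
    """Structurally invalid tracking XML (dangling edges, cycles, >1 root)."""


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Cell label → 3D position, arbitrary but consistent spatial units."""

    frame: pd.DataFrame  # index: cell label (str); columns x, y, z (float)

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dupes = sorted(self.frame.index[self.frame.index.duplicated()])
            raise TableFormatError(f"duplicate cell labels: {dupes[:5]}")
        if not np.isfinite(self.frame[["x", "y", "z"]].to_numpy()).all():
            raise TableFormatError("non-finite coordinate values")

    @property
    def labels(self) -> set[str]:
        return set(self.frame.index)

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    def position(self, cell: str) -> tuple[float, float, float]:
        row = self.frame.loc[cell]
        return (float(row.x), float(row.y), float(row.z))


@dataclass
class AnnotationTable:
    """One categorical annotation per cell (cell type, fate, saved clone...)."""

    mapping: dict[str, str]

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def cells_with(self, category: str) -> set[str]:
        return {c for c, a in self.mapping.items() if a == category}


@dataclass
class ExpressionTable:
    """Cell × gene matrix of non-negative expression values."""

    frame: pd.DataFrame  # index: cell label; columns: gene names

    @property
    def cells(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, gene: str) -> pd.Series:
        if gene not in self.frame.columns:
            near = gene_lookup(self, gene[:3]) if gene else []
            raise KeyError(
                f"unknown gene {gene!r}; nearest matches: {near[:5]}"
            )
        return self.frame[gene]


@dataclass
class JoinedDataset:
    """Bookkeeping of the label intersection between tree leaves and
    positioned cells. ``matched`` cells appear in both linked views."""

    tree: LineageTree
    cells: CellTable
    matched: set[str]
    tree_only: set[str]
    coords_only: set[str]
    messages: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_csv(text: str) -> pd.DataFrame:
    try:
        return pd.read_csv(
            io.StringIO(text), dtype={0: str}, skipinitialspace=True
        )
    except pd.errors.EmptyDataError:
        raise TableFormatError("empty CSV: no cells") from None


def read_coordinates(text: str) -> CellTable:
    """Parse a ``cell,X,Y,Z`` coordinates CSV."""
    df = _read_csv(text)
    header = [str(c).strip().lower() for c in df.columns]
    if header != ["cell", "x", "y", "z"]:
        raise TableFormatError(
            f"coordinates header must be cell,X,Y,Z (case-insensitive), "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise TableFormatError("coordinates file has no cells")
    df.columns = ["cell", "x", "y", "z"]
    df["cell"] = df["cell"].astype(str).str.strip()
    try:
        xyz = df[["x", "y", "z"]].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric coordinate: {exc}") from None
    out = xyz
    out.index = pd.Index(df["cell"], name="cell")
    return CellTable(out)


def write_coordinates(cells: CellTable) -> str:
    buf = io.StringIO()
    frame = cells.frame.rename(columns={"x": "X", "y": "Y", "z": "Z"})
    frame.to_csv(buf, index_label="cell")
    return buf.getvalue()


def read_annotations(text: str) -> AnnotationTable:
    """Parse a ``cell,annotation`` CSV; duplicate cells with conflicting
    annotations are an error listing the offenders."""
    df = _read_csv(text)
    header = [str(c).strip().lower() for c in df.columns]
    if header != ["cell", "annotation"]:
        raise TableFormatError(
            f"annotation header must be cell,annotation, got {list(df.columns)}"
        )
    df.columns = ["cell", "annotation"]
    df["cell"] = df["cell"].astype(str).str.strip()
    df["annotation"] = df["annotation"].astype(str).str.strip()
    mapping: dict[str, str] = {}
    conflicts: list[str] = []
    for cell, ann in zip(df["cell"], df["annotation"]):
        if cell in mapping and mapping[cell] != ann:
            conflicts.append(cell)
        mapping[cell] = ann
    if conflicts:
        raise TableFormatError(
            f"conflicting annotations for cells: {sorted(set(conflicts))[:10]}"
        )
    return AnnotationTable(mapping)


def write_selection_csv(selections) -> str:
    """Serialize saved selections as a ``cell,annotation`` CSV so they can be
    reloaded later as a cell-annotation file.

    ``selections`` is an iterable of ``(name, members)`` pairs (e.g.
    ``ViewState.saved_selections``) or an AnnotationTable.
    """
    lines = ["cell,annotation"]
    if isinstance(selections, AnnotationTable):
        pairs = sorted(selections.mapping.items())
        for cell, name in pairs:
            lines.append(f"{cell},{name}")
    else:
        for name, members in selections:
            for cell in sorted(members):
                lines.append(f"{cell},{name}")
    return "\n".join(lines) + "\n"


def read_expression(text: str) -> ExpressionTable:
    """Parse an expression CSV (first column ``cell``, one column per gene).

    Negative values are rejected; missing values become 0 (the table keeps a
    note of how many were filled).
    """
    # check the raw header first: pandas de-duplicates repeated column names
    raw_header = [h.strip() for h in text.splitlines()[0].split(",")] if text.strip() else []
    raw_genes = raw_header[1:]
    if len(set(raw_genes)) != len(raw_genes):
        dupes = sorted({g for g in raw_genes if raw_genes.count(g) > 1})
        raise TableFormatError(f"duplicate gene columns: {dupes}")
    df = _read_csv(text)
    if str(df.columns[0]).strip().lower() != "cell":
        raise TableFormatError(
            f"expression file must start with a 'cell' column, got {df.columns[0]!r}"
        )
    genes = [str(c).strip() for c in df.columns[1:]]
    if not genes:
        raise TableFormatError("expression file has no gene columns")
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise TableFormatError(f"duplicate gene columns: {dupes}")
    cells = df.iloc[:, 0].astype(str).str.strip()
    try:
        values = df.iloc[:, 1:].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric expression value: {exc}") from None
    values.columns = genes
    values.index = pd.Index(cells, name="cell")
    if values.isna().any().any():
        values = values.fillna(0.0)
    if (values.to_numpy() < 0).any():
        raise TableFormatError("negative expression values are not allowed")
    return ExpressionTable(values)


def write_expression(expr: ExpressionTable) -> str:
    buf = io.StringIO()
    expr.frame.to_csv(buf, index_label="cell")
    return buf.getvalue()


def gene_lookup(expr: ExpressionTable, prefix: str) -> list[str]:
    """Autofill: case-insensitive prefix matches, sorted, exact match first."""
    low = prefix.lower()
    hits = sorted(g for g in expr.genes if g.lower().startswith(low))
    exact = [g for g in hits if g.lower() == low]
    return exact + [g for g in hits if g.lower() != low]


# ---------------------------------------------------------------------------
# Join
# ---------------------------------------------------------------------------

def join(tree: LineageTree, cells: CellTable) -> JoinedDataset:
    """Match tree leaves to positioned cells by label.

    Partial coverage on either side is legal and reported as a warning; an
    empty intersection is an error naming sample labels from each side.
    """
    leaves = set(tree.leaf_labels)
    coords = cells.labels
    matched = leaves & coords
    tree_only = leaves - coords
    coords_only = coords - leaves
    if not matched:
        raise JoinError(
            "tree and coordinates share no cell labels; "
            f"tree leaves e.g. {sorted(leaves)[:5]}, "
            f"coordinate cells e.g. {sorted(coords)[:5]}"
        )
    messages: list[tuple[str, str]] = []
    if tree_only or coords_only:
        messages.append((
            "warning",
            f"partial join: {len(matched)} matched, "
            f"{len(tree_only)} tree-only, {len(coords_only)} coordinates-only",
        ))
    return JoinedDataset(tree, cells, matched, tree_only, coords_only, messages)


# ---------------------------------------------------------------------------
# MaMuT tracking XML
# ---------------------------------------------------------------------------

def import_mamut(xml_text: str | bytes) -> tuple[LineageTree, CellTable]:
    """Convert a single-file tracking XML (TrackMate/MaMuT family: a Model
    with AllSpots and AllTracks) into a lineage tree plus final coordinates.

    Spots linked by edges form tracks; chains of single-successor spots
    collapse into one tree edge whose relative length is the frame span.
    Spots with two or more successors become division nodes, spots without
    successors become leaves. Cells are labelled by the spot ``name``
    attribute when present, falling back to the numeric spot id. The
    returned CellTable holds each leaf's last-frame position — the 3D view
    shows the final time point only.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise MamutError(f"invalid XML: {exc}") from None

    spots: dict[int, dict] = {}
    for spot in root.iter("Spot"):
        sid = int(spot.get("ID"))
        spots[sid] = {
            "id": sid,
            "name": spot.get("name"),
            "frame": int(float(spot.get("FRAME"))),
            "x": float(spot.get("POSITION_X")),
            "y": float(spot.get("POSITION_Y")),
            "z": float(spot.get("POSITION_Z")),
        }
    if not spots:
        raise MamutError("no spots found (expected Model/AllSpots/.../Spot)")

    succ: dict[int, list[int]] = {sid: [] for sid in spots}
    pred: dict[int, int] = {}
    for edge in root.iter("Edge"):
        s = int(edge.get("SPOT_SOURCE_ID"))
        t = int(edge.get("SPOT_TARGET_ID"))
        if s not in spots or t not in spots:
            raise MamutError(f"edge references unknown spot: {s} -> {t}")
        if t in pred:
            raise MamutError(f"spot {t} has two incoming edges")
        succ[s].append(t)
        pred[t] = s

    roots = [sid for sid in spots if sid not in pred]
    if not roots:
        raise MamutError("no root spot: the track links form a cycle")
    if len(roots) > 1:
        names = [spots[r]["name"] or str(r) for r in sorted(roots)]
        raise MamutError(
            f"multiple disconnected tracks (roots: {names[:10]}); "
            "a single lineage is required"
        )

    # order successors deterministically by (frame, id)
    for sid in succ:
        succ[sid].sort(key=lambda t: (spots[t]["frame"], t))

    def label_of(spot: dict) -> str:
        return spot["name"] if spot["name"] else str(spot["id"])

    seen: set[int] = set()
    leaf_rows: list[tuple[str, float, float, float]] = []

    def build(sid: int, entry_frame: int) -> Node:
        """Follow the single-successor chain from sid; return the tree node
        at its end (division or leaf), with length = frame span."""
        cur = sid
        while True:
            if cur in seen:
                raise MamutError(f"cyclic track links at spot {cur}")
            seen.add(cur)
            nxt = succ[cur]
            if len(nxt) != 1:
                break
            cur = nxt[0]
        spot = spots[cur]
        node = Node(label_of(spot), branch_length=float(spot["frame"] - entry_frame))
        if not succ[cur]:
            leaf_rows.append((node.label, spot["x"], spot["y"], spot["z"]))
        for child in succ[cur]:
            node.add_child(build(child, spot["frame"]))
        return node

    root_spot = spots[roots[0]]
    tree_root = build(roots[0], root_spot["frame"])
    tree = LineageTree(tree_root, "relative")

    frame = pd.DataFrame(leaf_rows, columns=["cell", "x", "y", "z"])
    frame = frame.set_index("cell")
    return tree, CellTable(frame)
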