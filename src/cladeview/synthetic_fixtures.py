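"""Synthetic lineages, positions, annotations, expression and tracking XML.

Everything the readers accept can be generated here, deterministically from
a seed, so the whole package is testable without downloaded data. The
simulator is a pure-birth (Yule-type) process: lineages wait a random (or
fixed) time and divide in two; its division log records exactly which
lineages are alive at any time and serves as ground truth for time cuts.
Positions come from a branching random walk whose ``coherence`` parameter
controls how strongly sibling subtrees drift apart as coherent clones —
emulating the clonally contiguous territories seen in real embryos, not any
particular morphogenetic mechanism.

``fixture_suite`` packages four small datasets covering the feature
combinations a lineage browser must handle: Newick or JSON input; relative,
absolute or no branch lengths; partial coordinate coverage; annotations;
gene expression.
"""

from __future__ import annotations

import bisect
import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .tree_io import LineageTree, Node, to_newick, to_json, convert_bl_mode
from .lineage_ops import clones_at_division_depth, clone
from .spatial_join import (
    AnnotationTable,
    CellTable,
    ExpressionTable,
    write_coordinates,
    write_expression,
    write_selection_csv,
)


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``division_waiting`` is ``("exponential", rate)`` (memoryless waiting,
    the default) or ``("fixed", dt)`` (synchronous divisions, yielding
    complete binary trees for power-of-two leaf counts). ``coherence`` in
    [0, 1] balances persistent per-subtree drift against isotropic noise in
    the spatial walk. ``polytomy_rate`` is the probability that a daughter
    divides again instantly; the resulting zero-length internal edge is
    collapsed, leaving a polytomy.
    """

    n_leaves: int = 64
    seed: int = 0
    division_waiting: tuple[str, float] = ("exponential", 1.0)
    spatial_step: float = 1.0
    coherence: float = 0.8
    n_genes: int = 5
    n_marker_clades: int = 2
    polytomy_rate: float = 0.0

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        kind, param = self.division_waiting
        if kind not in ("exponential", "fixed") or param <= 0:
            raise ValueError(f"bad division_waiting {self.division_waiting!r}")
        if not (0.0 <= self.coherence <= 1.0):
            raise ValueError("coherence must be in [0, 1]")
        if not (0.0 <= self.polytomy_rate < 1.0):
            raise ValueError("polytomy_rate must be in [0, 1)")
        if self.spatial_step < 0:
            raise ValueError("spatial_step must be >= 0")


@dataclass
class DivisionLog:
    """Ground truth from the simulator: sorted division times plus the
    final time at which every leaf persists."""

    division_times: list[float]
    final_time: float

    def alive_at(self, t: float) -> int:
        """Lineages alive at ``t``: a mother remains alive up to and
        including its division instant; terminated cells persist forever."""
        return 1 + bisect.bisect_left(self.division_times, t)


def _mean_waiting(cfg: SimConfig) -> float:
    kind, param = cfg.division_waiting
    return param if kind == "fixed" else 1.0 / param


def simulate_lineage(cfg: SimConfig) -> tuple[LineageTree, DivisionLog]:
    """Grow a lineage by a pure-birth process until ``cfg.n_leaves`` cells.

    Returns the tree with *relative* branch lengths (waiting times) and the
    division log. Leaves persist one mean waiting time past the last
    division, so every terminal branch has positive length.
    """
    rng = np.random.default_rng(cfg.seed)
    kind, param = cfg.division_waiting

    def waiting(instant_allowed: bool) -> float:
        if instant_allowed and cfg.polytomy_rate > 0 \
                and rng.random() < cfg.polytomy_rate:
            return 0.0
        return param if kind == "fixed" else float(rng.exponential(1.0 / param))

    root = Node("c1")
    if cfg.n_leaves == 1:
        root.branch_length = _mean_waiting(cfg)
        return (LineageTree(root, "relative"),
                DivisionLog([], root.branch_length))

    birth: dict[int, float] = {id(root): 0.0}
    division: dict[int, float] = {}
    counter = 1
    # heap of (scheduled division time, creation order, node)
    heap: list[tuple[float, int, Node]] = [(waiting(False), 0, root)]
    alive = 1
    division_times: list[float] = []
    while alive < cfg.n_leaves:
        t_div, _, node = heapq.heappop(heap)
        division[id(node)] = t_div
        division_times.append(t_div)
        for _ in range(2):
            counter += 1
            child = Node(f"c{counter}")
            node.add_child(child)
            birth[id(child)] = t_div
            heapq.heappush(heap, (t_div + waiting(True), counter, child))
        alive += 1

    division_times.sort()
    final_time = division_times[-1] + _mean_waiting(cfg)
    stack = [root]
    while stack:
        node = stack.pop()
        end = division[id(node)] if node.children else final_time
        node.branch_length = end - birth[id(node)]
        stack.extend(node.children)

    tree_root = _collapse_zero_internal(root) if cfg.polytomy_rate > 0 else root
    return LineageTree(tree_root, "relative"), DivisionLog(division_times, final_time)


def _collapse_zero_internal(root: Node) -> Node:
    """Merge zero-length internal edges into their parents (polytomies)."""

    def rebuild(node: Node) -> Node:
        new = Node(node.label, branch_length=node.branch_length)
        for c in node.children:
            built = rebuild(c)
            if built.children and built.branch_length is not None \
                    and built.branch_length <= 1e-12:
                for gc in list(built.children):
                    gc.parent = None
                    new.add_child(gc)
            else:
                new.add_child(built)
        return new

    return rebuild(root)


# ---------------------------------------------------------------------------
# Spatial placement
# ---------------------------------------------------------------------------

def walk_positions(tree: LineageTree, cfg: SimConfig) -> dict[str, np.ndarray]:
    """Branching random walk over every node of the tree.

    Each daughter inherits its mother's position plus one displacement of
    scale ``spatial_step`` composed of a heritable per-branch drift
    direction (weight ``coherence``) and isotropic Gaussian noise (weight
    ``1 − coherence``). Sibling drifts are independent, so sister subtrees
    diverge while each clone stays spatially coherent.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    positions: dict[str, np.ndarray] = {tree.root.label: np.zeros(3)}
    drifts: dict[str, np.ndarray] = {tree.root.label: np.zeros(3)}
    for node in tree.iter_nodes():
        if node.parent is None:
            continue
        parent_drift = drifts[node.parent.label]
        fresh = rng.standard_normal(3)
        blended = 0.6 * parent_drift + fresh
        norm = np.linalg.norm(blended)
        drift = blended / norm if norm > 0 else blended
        drifts[node.label] = drift
        noise = rng.standard_normal(3)
        step = cfg.spatial_step * (cfg.coherence * drift
                                   + (1.0 - cfg.coherence) * noise)
        positions[node.label] = positions[node.parent.label] + step
    return positions


def place_cells(tree: LineageTree, cfg: SimConfig) -> CellTable:
    """Leaf positions from the branching random walk as a CellTable."""
    positions = walk_positions(tree, cfg)
    labels = tree.leaf_labels
    frame = pd.DataFrame(
        [positions[lbl] for lbl in labels],
        index=pd.Index(labels, name="cell"),
        columns=["x", "y", "z"],
    )
    return CellTable(frame)


# ---------------------------------------------------------------------------
# Annotations and expression
# ---------------------------------------------------------------------------

def _marker_clades(tree: LineageTree, cfg: SimConfig, rng) -> list[str]:
    """Choose founder labels among non-singleton depth-2 clones."""
    part = clones_at_division_depth(tree, 2)
    founders = sorted(f for f, members in part.groups.items()
                      if len(members) >= 2) or sorted(part.groups)
    if cfg.n_marker_clades > len(founders):
        raise ValueError(
            f"n_marker_clades={cfg.n_marker_clades} exceeds the "
            f"{len(founders)} available depth-2 clades"
        )
    idx = rng.choice(len(founders), size=cfg.n_marker_clades, replace=False)
    return [founders[i] for i in sorted(idx)]


def annotate_clades(tree: LineageTree, cfg: SimConfig) -> tuple[AnnotationTable, dict[str, str]]:
    """Give each of ``n_marker_clades`` depth-2 clades a fate label.

    Returns the table (every other cell is labelled ``"other"``) and the
    ground-truth fate → founder mapping for tests.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    founders = _marker_clades(tree, cfg, rng)
    mapping = {cell: "other" for cell in tree.leaf_labels}
    truth: dict[str, str] = {}
    for i, founder in enumerate(founders, start=1):
        fate = f"fate_{i}"
        truth[fate] = founder
        for cell in clone(tree, founder):
            mapping[cell] = fate
    return AnnotationTable(mapping), truth


def express_markers(tree: LineageTree, cfg: SimConfig) -> tuple[ExpressionTable, dict[str, str]]:
    """One log-normally noisy marker gene per chosen clade (mean 10 inside,
    0.1 outside) plus background genes up to ``n_genes``.

    Returns the table and the ground-truth gene → founder mapping.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    founders = _marker_clades(tree, cfg, rng)
    cells = tree.leaf_labels
    columns: dict[str, np.ndarray] = {}
    truth: dict[str, str] = {}
    sigma = 0.5
    for i, founder in enumerate(founders, start=1):
        gene = f"marker_{i}"
        truth[gene] = founder
        inside = clone(tree, founder)
        mu = np.where([c in inside for c in cells], np.log(10.0), np.log(0.1))
        columns[gene] = np.exp(mu + sigma * rng.standard_normal(len(cells)))
    for j in range(len(founders) + 1, cfg.n_genes + 1):
        columns[f"gene_{j}"] = np.exp(
            np.log(1.0) + sigma * rng.standard_normal(len(cells))
        )
    frame = pd.DataFrame(columns, index=pd.Index(cells, name="cell"))
    return ExpressionTable(frame), truth


# ---------------------------------------------------------------------------
# Tracking XML (MaMuT/TrackMate-family schema)
# ---------------------------------------------------------------------------

def write_mamut_xml(
    tree: LineageTree,
    positions: Optional[dict[str, np.ndarray]] = None,
    cfg: Optional[SimConfig] = None,
) -> str:
    """Emit a single-file tracking XML equivalent to the lineage.

    The tree must carry relative integer branch lengths (frames). Each edge
    of length L becomes a chain of L spots at consecutive frames, linearly
    interpolated between the parent's and the node's position; consecutive
    spots are linked by edges. Importing the result recovers the tree
    (isomorphic, labels preserved) and the final leaf positions exactly.
    """
    if tree.bl_mode != "relative":
        raise ValueError("write_mamut_xml requires relative branch lengths")
    if positions is None:
        positions = walk_positions(tree, cfg or SimConfig(seed=0))
    spots: list[dict] = []
    links: list[tuple[int, int]] = []
    next_id = [0]

    def emit(name: str, frame: int, pos: np.ndarray) -> int:
        sid = next_id[0]
        next_id[0] += 1
        spots.append({"id": sid, "name": name, "frame": frame,
                      "x": float(pos[0]), "y": float(pos[1]), "z": float(pos[2])})
        return sid

    def span_of(node: Node) -> int:
        bl = node.branch_length or 0.0
        span = int(round(bl))
        if abs(bl - span) > 1e-9 or (node.parent is not None and span < 1):
            raise ValueError(
                f"branch length of {node.label!r} must be a positive "
                f"integer frame count, got {bl}"
            )
        return span

    def walk(node: Node, parent_sid: int, parent_frame: int,
             parent_pos: np.ndarray) -> None:
        span = span_of(node)
        end_pos = positions[node.label]
        prev_sid, prev_frame = parent_sid, parent_frame
        for step in range(1, span + 1):
            frac = step / span
            pos = parent_pos + frac * (end_pos - parent_pos)
            name = node.label if step == span else f"sp{next_id[0]}"
            sid = emit(name, parent_frame + step, pos)
            links.append((prev_sid, sid))
            prev_sid = sid
        for child in node.children:
            walk(child, prev_sid, parent_frame + span, end_pos)

    root = tree.root
    root_pos = positions[root.label]
    root_sid = emit(root.label, 0, root_pos)
    for child in root.children:
        walk(child, root_sid, 0, root_pos)

    frames: dict[int, list[dict]] = {}
    for spot in spots:
        frames.setdefault(spot["frame"], []).append(spot)
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<TrackMate version="7.0.0">', "  <Model spatialunits=\"pixel\" "
             "timeunits=\"frame\">", "    <AllSpots>"]
    for frame in sorted(frames):
        lines.append(f'      <SpotsInFrame frame="{frame}">')
        for spot in frames[frame]:
            lines.append(
                f'        <Spot ID="{spot["id"]}" name="{spot["name"]}" '
                f'FRAME="{spot["frame"]}" POSITION_X="{spot["x"]:.9g}" '
                f'POSITION_Y="{spot["y"]:.9g}" POSITION_Z="{spot["z"]:.9g}"/>'
            )
        lines.append("      </SpotsInFrame>")
    lines.append("    </AllSpots>")
    lines.append("    <AllTracks>")
    lines.append('      <Track name="Track_0" TRACK_ID="0">')
    for src, tgt in links:
        lines.append(
            f'        <Edge SPOT_SOURCE_ID="{src}" SPOT_TARGET_ID="{tgt}"/>'
        )
    lines.append("      </Track>")
    lines.append("    </AllTracks>")
    lines.append("  </Model>")
    lines.append("</TrackMate>")
    return "\n".join(lines) + "\n"


def tracking_config(n_leaves: int = 12, seed: int = 0) -> SimConfig:
    """A SimConfig whose trees have integer frame branch lengths, suitable
    for round-tripping through tracking XML."""
    return SimConfig(
        n_leaves=n_leaves, seed=seed, division_waiting=("fixed", 2.0)
    )


def integer_frame_tree(n_leaves: int = 12, seed: int = 0) -> tuple[LineageTree, SimConfig]:
    """A random-topology tree with integer branch lengths (frames >= 1)."""
    cfg = SimConfig(n_leaves=n_leaves, seed=seed)
    tree, _log = simulate_lineage(cfg)
    for node in tree.iter_nodes():
        bl = node.branch_length or 0.0
        node.branch_length = float(max(1, round(bl * 3))) if node.parent else 0.0
    return tree, cfg


# ---------------------------------------------------------------------------
# Packaged fixture suite
# ---------------------------------------------------------------------------

@dataclass
class FixtureDataset:
    """One packaged mini-dataset: tree text plus optional side files."""

    name: str
    tree_format: str            # "newick" | "json"
    bl_mode: str                # "none" | "relative" | "absolute"
    tree_text: str
    coords_csv: str
    annotations_csv: Optional[str] = None
    expression_csv: Optional[str] = None
    tree_text_alt: Optional[str] = None  # same topology, the other format

    def write_to(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ext = "nwk" if self.tree_format == "newick" else "json"
        (directory / f"tree.{ext}").write_text(self.tree_text)
        (directory / "coordinates.csv").write_text(self.coords_csv)
        if self.annotations_csv:
            (directory / "annotations.csv").write_text(self.annotations_csv)
        if self.expression_csv:
            (directory / "expression.csv").write_text(self.expression_csv)
        if self.tree_text_alt:
            alt = "json" if ext == "nwk" else "nwk"
            (directory / f"tree.{alt}").write_text(self.tree_text_alt)
        return directory


def _annotations_csv(table: AnnotationTable) -> str:
    return write_selection_csv(table)


def _clamp_markers(tree: LineageTree, cfg: SimConfig) -> SimConfig:
    """Cap n_marker_clades at what the tree's depth-2 cut actually offers."""
    part = clones_at_division_depth(tree, 2)
    available = sum(1 for m in part.groups.values() if len(m) >= 2) \
        or len(part.groups)
    if cfg.n_marker_clades <= available:
        return cfg
    return SimConfig(
        n_leaves=cfg.n_leaves, seed=cfg.seed,
        division_waiting=cfg.division_waiting, spatial_step=cfg.spatial_step,
        coherence=cfg.coherence, n_genes=cfg.n_genes,
        n_marker_clades=available, polytomy_rate=cfg.polytomy_rate,
    )


def fixture_suite(seed: int = 0) -> list[FixtureDataset]:
    """Four ~100-cell datasets spanning the supported feature matrix.

    * ``worm-like`` — Newick, relative branch lengths, annotations, and
      coordinates for only a strict subset of the cells (partial coverage,
      as when positions are mapped for some of a published lineage).
    * ``gastrula-like`` — Newick, no branch lengths, annotations *and*
      gene expression, full coordinates.
    * ``limb-like`` — JSON (with a Newick twin), absolute branch lengths.
    * ``organoid-like`` — JSON only: topology and coordinates, nothing else.
    """
    datasets: list[FixtureDataset] = []

    # worm-like: partial coordinate coverage
    cfg = SimConfig(n_leaves=100, seed=seed, n_marker_clades=3)
    tree, _ = simulate_lineage(cfg)
    cells = place_cells(tree, cfg)
    rng = np.random.default_rng(seed + 10)
    keep = sorted(rng.choice(tree.leaf_labels, size=64, replace=False))
    partial = CellTable(cells.frame.loc[keep])
    ann, _truth = annotate_clades(tree, _clamp_markers(tree, cfg))
    datasets.append(FixtureDataset(
        name="worm-like", tree_format="newick", bl_mode="relative",
        tree_text=to_newick(tree),
        coords_csv=write_coordinates(partial),
        annotations_csv=_annotations_csv(ann),
    ))

    # gastrula-like: annotations + expression, no branch lengths
    cfg = SimConfig(n_leaves=110, seed=seed + 1, n_marker_clades=3, n_genes=8)
    tree, _ = simulate_lineage(cfg)
    cells = place_cells(tree, cfg)
    mcfg = _clamp_markers(tree, cfg)
    ann, _ = annotate_clades(tree, mcfg)
    expr, _ = express_markers(tree, mcfg)
    bare = LineageTree(_strip_lengths(tree.root), "none")
    datasets.append(FixtureDataset(
        name="gastrula-like", tree_format="newick", bl_mode="none",
        tree_text=to_newick(bare),
        coords_csv=write_coordinates(cells),
        annotations_csv=_annotations_csv(ann),
        expression_csv=write_expression(expr),
    ))

    # limb-like: absolute branch lengths, JSON and Newick twins
    cfg = SimConfig(n_leaves=90, seed=seed + 2)
    tree, _ = simulate_lineage(cfg)
    cells = place_cells(tree, cfg)
    abs_tree = convert_bl_mode(tree, "absolute")
    datasets.append(FixtureDataset(
        name="limb-like", tree_format="json", bl_mode="absolute",
        tree_text=to_json(abs_tree),
        coords_csv=write_coordinates(cells),
        tree_text_alt=to_newick(abs_tree),
    ))

    # organoid-like: topology + coordinates only
    cfg = SimConfig(n_leaves=100, seed=seed + 3, polytomy_rate=0.15)
    tree, _ = simulate_lineage(cfg)
    cells = place_cells(tree, cfg)
    bare = LineageTree(_strip_lengths(tree.root), "none")
    datasets.append(FixtureDataset(
        name="organoid-like", tree_format="json", bl_mode="none",
        tree_text=to_json(bare),
        coords_csv=write_coordinates(cells),
    ))
    return datasets


def _strip_lengths(root: Node) -> Node:
    new = Node(root.label)
    for c in root.children:
        new.add_child(_strip_lengths(c))
    return new
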