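"""Deterministic layout and styling for the two linked views.

The static exports draw the lineage tree on the left and an orthographic
projection of the 3D cell positions on the right; a static image cannot
rotate, so the projection angle is part of the Scene (azimuth/elevation),
while free rotation lives in the standalone HTML export. Rendering is a
pure function of the Scene: identical Scenes produce byte-identical SVG.

Exactly one overlay is active per Scene — clone partition, lineage
relationship, categorical annotation, or a gene's expression heatmap — and
the colour assigned to a cell is identical in both panels (linked views).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .tree_io import LineageTree, Node, node_times
from .lineage_ops import (
    ClonePartition,
    RelationshipMap,
    ViewState,
    clone,
    descendant_summary,
)
from .spatial_join import AnnotationTable, ExpressionTable, JoinedDataset

#: 12 maximally distinct categorical colours (colour-blind-aware hues).
DEFAULT_PALETTE = (
    "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231", "#911eb4",
    "#46f0f0", "#f032e6", "#bcf60c", "#fabebe", "#008080", "#e6beff",
)

#: Cells outside every selected group.
NEUTRAL_COLOUR = "#d3d3d3"

#: Sequential scale for expression heatmaps and relationship levels
#: (viridis anchor points, interpolated linearly in RGB).
_SEQUENTIAL = (
    (0.0, (68, 1, 84)),
    (0.25, (59, 82, 139)),
    (0.5, (33, 145, 140)),
    (0.75, (94, 201, 98)),
    (1.0, (253, 231, 37)),
)


def sequential_colour(t: float) -> str:
    """Interpolate the sequential scale at ``t`` in [0, 1]."""
    t = min(1.0, max(0.0, t))
    for (t0, c0), (t1, c1) in zip(_SEQUENTIAL, _SEQUENTIAL[1:]):
        if t <= t1:
            w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            rgb = tuple(round(a + w * (b - a)) for a, b in zip(c0, c1))
            return "#%02x%02x%02x" % rgb
    return "#%02x%02x%02x" % _SEQUENTIAL[-1][1]


Overlay = Union[
    None, ClonePartition, RelationshipMap, AnnotationTable,
    tuple[ExpressionTable, str],
]


@dataclass
class Scene:
    """A reproducible description of one linked view."""

    joined: JoinedDataset
    view: ViewState = field(default_factory=ViewState)
    layout_mode: str = "cladogram"  # or "branch_length"
    overlay: Overlay = None
    sphere_radius: float = 5.0
    palette: tuple[str, ...] = DEFAULT_PALETTE
    azimuth: float = 35.0   # degrees, for the static orthographic projection
    elevation: float = 20.0
    messages: list[tuple[str, str]] = field(default_factory=list)

    def colour_map(self) -> dict[str, str]:
        """One colour per cell, identical across both panels."""
        tree = self.joined.tree
        cells = set(tree.leaf_labels) | self.joined.coords_only
        cmap = {cell: NEUTRAL_COLOUR for cell in cells}
        ov = self.overlay
        if ov is None:
            return cmap
        if isinstance(ov, ClonePartition):
            groups = {k: ov.groups[k] for k in sorted(ov.groups)}
            cmap.update(assign_colours(groups, self.palette, self.messages))
        elif isinstance(ov, RelationshipMap):
            top = max(ov.level.values()) if ov.level else 1
            for cell, lev in ov.level.items():
                cmap[cell] = sequential_colour(lev / top if top else 0.0)
        elif isinstance(ov, AnnotationTable):
            groups = {cat: ov.cells_with(cat) for cat in ov.categories}
            cmap.update(assign_colours(groups, self.palette, self.messages))
        else:
            expr, gene = ov
            gene_map, _legend = expression_scale(expr, gene, self.messages)
            cmap.update(gene_map)
        return cmap

    def legend(self) -> Optional[dict]:
        ov = self.overlay
        if isinstance(ov, tuple):
            expr, gene = ov
            _, legend = expression_scale(expr, gene)
            return legend
        if isinstance(ov, RelationshipMap):
            return {"kind": "relationship", "focal": ov.focal,
                    "max_level": max(ov.level.values(), default=0)}
        return None


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass
class TreeLayout:
    """Node positions for drawing: x is the depth/time coordinate, y the
    leaf-order coordinate (one unit per displayed leaf slot)."""

    mode: str
    x: dict[str, float]
    y: dict[str, float]
    leaf_order: list[str]  # displayed leaf slots, top to bottom
    collapsed: frozenset[str] = frozenset()


def layout_tree(
    tree: LineageTree, view: Optional[ViewState] = None, mode: str = "cladogram",
    messages: Optional[list[tuple[str, str]]] = None,
) -> TreeLayout:
    """Deterministic tree layout.

    Cladogram mode: internal x equals division depth, all leaf slots share
    the deepest x. Branch-length mode: x equals the node's time from the
    root (falls back to cladogram with a warning when the tree carries no
    lengths). Collapsed subtrees occupy one slot; pruned subtrees are absent.
    """
    view = view or ViewState()
    if mode == "branch_length" and tree.bl_mode == "none":
        if messages is not None:
            messages.append(("warning",
                             "tree has no branch lengths; falling back to cladogram"))
        mode = "cladogram"
    if mode not in ("cladogram", "branch_length"):
        raise ValueError(f"unknown layout mode {mode!r}")

    times = node_times(tree) if mode == "branch_length" else None

    x: dict[str, float] = {}
    y: dict[str, float] = {}
    leaf_order: list[str] = []
    max_display_depth = 0

    def measure(node: Node, depth: int) -> None:
        nonlocal max_display_depth
        if node.label in view.pruned:
            return
        terminal = node.is_leaf or node.label in view.collapsed
        if terminal:
            max_display_depth = max(max_display_depth, depth)
            return
        for c in node.children:
            measure(c, depth + 1)

    measure(tree.root, 0)

    def place(node: Node, depth: int) -> Optional[float]:
        """Assign y (leaf slot index or mean of children); returns y or None
        when the subtree is entirely pruned."""
        if node.label in view.pruned:
            return None
        terminal = node.is_leaf or node.label in view.collapsed
        if terminal:
            yy = float(len(leaf_order))
            leaf_order.append(node.label)
        else:
            child_ys = [cy for c in node.children
                        if (cy := place(c, depth + 1)) is not None]
            if not child_ys:  # all children pruned: render as a slot
                yy = float(len(leaf_order))
                leaf_order.append(node.label)
                terminal = True
            else:
                yy = sum(child_ys) / len(child_ys)
        y[node.label] = yy
        if times is not None:
            x[node.label] = times[node.label]
        else:
            x[node.label] = float(max_display_depth if terminal else depth)
        return yy

    place(tree.root, 0)
    return TreeLayout(mode, x, y, leaf_order, view.collapsed)


# ---------------------------------------------------------------------------
# Colour assignment
# ---------------------------------------------------------------------------

def assign_colours(
    groups, palette=DEFAULT_PALETTE,
    messages: Optional[list[tuple[str, str]]] = None,
) -> dict[str, str]:
    """Map each cell of each group to a colour, cycling the palette when
    there are more groups than colours (with a warning).

    ``groups`` is an ordered mapping name → member set, or an ordered list
    of member sets. Stable: the same groups in the same order always get the
    same colours.
    """
    if isinstance(groups, dict):
        ordered = list(groups.values())
    else:
        ordered = list(groups)
    if len(ordered) > len(palette) and messages is not None:
        messages.append(("warning",
                         f"{len(ordered)} groups exceed the {len(palette)}-colour "
                         "palette; colours will repeat"))
    cmap: dict[str, str] = {}
    for i, members in enumerate(ordered):
        colour = palette[i % len(palette)]
        for cell in members:
            cmap[cell] = colour
    return cmap


def expression_scale(
    expr: ExpressionTable, gene: str,
    messages: Optional[list[tuple[str, str]]] = None,
    cells: Optional[set[str]] = None,
) -> tuple[dict[str, str], dict]:
    """Heatmap colours for one gene: a linear map from [min, max] of its
    values (over ``cells`` when given) onto the sequential scale, plus a
    legend recording the numeric range."""
    values = expr.values_for(gene)
    if cells is not None:
        values = values[values.index.isin(cells)]
    vmin, vmax = float(values.min()), float(values.max())
    degenerate = math.isclose(vmin, vmax)
    if degenerate and messages is not None:
        messages.append(("warning",
                         f"gene {gene!r} has a degenerate range [{vmin}, {vmax}]; "
                         "all cells share one colour"))
    cmap = {}
    for cell, v in values.items():
        t = 0.0 if degenerate else (float(v) - vmin) / (vmax - vmin)
        cmap[cell] = sequential_colour(t)
    legend = {"kind": "expression", "gene": gene, "vmin": vmin, "vmax": vmax}
    return cmap, legend


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def _project(points: np.ndarray, azimuth: float, elevation: float) -> np.ndarray:
    """Orthographic projection of Nx3 points onto the viewing plane."""
    az, el = math.radians(azimuth), math.radians(elevation)
    # rotate about z by azimuth, then about x by elevation; keep (x, z)
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    rx = np.array([[1, 0, 0],
                   [0, math.cos(el), -math.sin(el)],
                   [0, math.sin(el), math.cos(el)]])
    rot = points @ rz.T @ rx.T
    return rot[:, [0, 2]]


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_TREE_W, _PANEL_3D_W, _MARGIN = 540.0, 520.0, 40.0


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _scene_geometry(scene: Scene):
    """Shared geometry for SVG and PNG: tree segments, leaf markers and
    projected 3D points, all in canvas coordinates."""
    tree = scene.joined.tree
    layout = layout_tree(tree, scene.view, scene.layout_mode, scene.messages)
    n_slots = max(len(layout.leaf_order), 1)
    height = max(320.0, 16.0 * n_slots + 2 * _MARGIN)
    width = _TREE_W + _PANEL_3D_W + 3 * _MARGIN

    xmax = max(layout.x.values()) or 1.0
    sx = (_TREE_W - 2 * _MARGIN) / xmax
    sy = (height - 2 * _MARGIN) / max(n_slots - 1, 1)

    def tx(v: float) -> float:
        return _MARGIN + v * sx

    def ty(v: float) -> float:
        return _MARGIN + v * sy

    segments = []  # ((x1,y1),(x2,y2))
    for label, yy in layout.y.items():
        node = tree.node(label)
        p = node.parent
        if p is None or p.label not in layout.y:
            continue
        px, py = tx(layout.x[p.label]), ty(layout.y[p.label])
        cx, cy = tx(layout.x[label]), ty(yy)
        segments.append(((px, py), (px, cy)))
        segments.append(((px, cy), (cx, cy)))

    cmap = scene.colour_map()
    markers = []  # (label, x, y, colour, is_collapsed, total, on_viewer)
    for label in layout.leaf_order:
        node = tree.node(label)
        collapsed = label in layout.collapsed and not node.is_leaf
        colour = cmap.get(label, NEUTRAL_COLOUR)
        _, total, on_viewer = descendant_summary(tree, label, scene.joined)
        markers.append((label, tx(layout.x[label]), ty(layout.y[label]),
                        colour, collapsed, total, on_viewer))

    # 3D panel: project matched cells (and coords-only cells) orthographically
    frame = scene.joined.cells.frame
    shown = sorted(scene.joined.matched | scene.joined.coords_only)
    pts3d = []
    if shown:
        arr = frame.loc[shown, ["x", "y", "z"]].to_numpy(dtype=float)
        arr = arr - arr.mean(axis=0)
        proj = _project(arr, scene.azimuth, scene.elevation)
        span = float(np.abs(proj).max()) or 1.0
        scale = (_PANEL_3D_W / 2 - _MARGIN) / span
        cx0 = _TREE_W + 2 * _MARGIN + _PANEL_3D_W / 2
        cy0 = height / 2
        # painter's order: far to near along the rotated depth axis
        order = np.argsort(proj[:, 0], kind="stable")
        for i in order:
            cell = shown[i]
            pts3d.append((cell,
                          cx0 + proj[i, 0] * scale,
                          cy0 - proj[i, 1] * scale,
                          cmap.get(cell, NEUTRAL_COLOUR)))
    return layout, width, height, segments, markers, pts3d


def render_svg(scene: Scene) -> str:
    """Render the linked view as deterministic standalone SVG text."""
    layout, width, height, segments, markers, pts3d = _scene_geometry(scene)
    tree = scene.joined.tree
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        '<rect width="100%" height="100%" fill="white"/>',
        '<g id="lineage-panel" stroke="#555555" stroke-width="1" fill="none">',
    ]
    for (x1, y1), (x2, y2) in segments:
        out.append(f'<path d="M{_fmt(x1)},{_fmt(y1)} L{_fmt(x2)},{_fmt(y2)}"/>')
    out.append("</g>")
    out.append('<g id="lineage-cells">')
    for label, x, y, colour, collapsed, total, on_viewer in markers:
        shape_r = 4.5 if collapsed else 3.0
        title = f"{label}: {total} descendants, {on_viewer} on 3D viewer"
        out.append(
            f'<circle class="treecell" data-cell="{_esc(label)}" '
            f'cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(shape_r)}" '
            f'fill="{colour}" stroke="#333333" stroke-width="0.5">'
            f"<title>{_esc(title)}</title></circle>"
        )
        if collapsed:
            out.append(
                f'<text x="{_fmt(x + 7)}" y="{_fmt(y + 3)}" font-size="9" '
                f'font-family="sans-serif" fill="#333333">'
                f"{_esc(label)} (+{total})</text>"
            )
    out.append("</g>")
    out.append('<g id="cells-3d">')
    for cell, x, y, colour in pts3d:
        out.append(
            f'<circle class="cell3d" data-cell="{_esc(cell)}" '
            f'cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(scene.sphere_radius)}" '
            f'fill="{colour}" fill-opacity="0.85" stroke="#444444" '
            f'stroke-width="0.4"><title>{_esc(cell)}</title></circle>'
        )
    out.append("</g>")
    legend = scene.legend()
    if legend and legend["kind"] == "expression":
        out.append(
            f'<text x="{_fmt(_TREE_W + 2 * _MARGIN)}" y="{_fmt(height - 10)}" '
            f'font-size="11" font-family="sans-serif" fill="#333333">'
            f'{_esc(legend["gene"])}: {legend["vmin"]:.3g} – {legend["vmax"]:.3g}'
            "</text>"
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _render_png(scene: Scene, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout, width, height, segments, markers, pts3d = _scene_geometry(scene)
    fig, ax = plt.subplots(figsize=(width / 96, height / 96), dpi=96)
    for (x1, y1), (x2, y2) in segments:
        ax.plot([x1, x2], [y1, y2], color="#555555", linewidth=1)
    for label, x, y, colour, collapsed, *_ in markers:
        ax.scatter([x], [y], s=60 if collapsed else 28, c=colour,
                   edgecolors="#333333", linewidths=0.5, zorder=3)
    for cell, x, y, colour in pts3d:
        ax.scatter([x], [y], s=scene.sphere_radius ** 2, c=colour,
                   alpha=0.85, edgecolors="#444444", linewidths=0.4, zorder=3)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_static(scene: Scene, fmt: str, path: str) -> str:
    """Write the linked view to ``path`` as ``"svg"`` or ``"png"``.

    SVG output is a pure function of the Scene (byte-identical across runs).
    Returns the path written.
    """
    if fmt == "svg":
        svg = render_svg(scene)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(svg)
    elif fmt == "png":
        _render_png(scene, path)
    else:
        raise ValueError(f"format must be 'svg' or 'png', got {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Standalone interactive HTML
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>cladeview scene</title>
<style>
body {{ font-family: sans-serif; margin: 10px; }}
#panels {{ display: flex; gap: 16px; }}
#hover {{ min-height: 1.3em; color: #333; font-size: 13px; }}
circle.treecell, circle.cell3d {{ cursor: pointer; }}
circle.hl {{ stroke: #000000; stroke-width: 2px; }}
</style></head>
<body>
<div id="hover">hover a cell; click to highlight its clone in both panels</div>
<div id="panels">
<svg id="tree" width="{tree_w}" height="{h}"></svg>
<canvas id="c3d" width="{w3d}" height="{h}"></canvas>
</div>
<script>
const DATA = {data_json};
const R = {sphere_radius};
(function() {{
  const svgNS = "http://www.w3.org/2000/svg";
  const tree = document.getElementById("tree");
  for (const s of DATA.segments) {{
    const p = document.createElementNS(svgNS, "path");
    p.setAttribute("d", `M${{s[0][0]}},${{s[0][1]}} L${{s[1][0]}},${{s[1][1]}}`);
    p.setAttribute("stroke", "#555"); p.setAttribute("fill", "none");
    tree.appendChild(p);
  }}
  const hover = document.getElementById("hover");
  for (const m of DATA.markers) {{
    const c = document.createElementNS(svgNS, "circle");
    c.setAttribute("class", "treecell"); c.dataset.cell = m.cell;
    c.setAttribute("cx", m.x); c.setAttribute("cy", m.y);
    c.setAttribute("r", m.collapsed ? 4.5 : 3);
    c.setAttribute("fill", m.colour); c.setAttribute("stroke", "#333");
    c.addEventListener("mouseenter", () =>
      hover.textContent = `${{m.cell}} — ${{m.total}} descendants, ` +
                          `${{m.on_viewer}} on 3D viewer`);
    c.addEventListener("click", () => highlight(DATA.clones[m.cell] || [m.cell]));
    tree.appendChild(c);
  }}
  const canvas = document.getElementById("c3d");
  const ctx = canvas.getContext("2d");
  let az = {azimuth} * Math.PI / 180, el = {elevation} * Math.PI / 180;
  let selected = new Set();
  function project(p) {{
    const ca = Math.cos(az), sa = Math.sin(az);
    const ce = Math.cos(el), se = Math.sin(el);
    const x = p[0] * ca - p[1] * sa, y0 = p[0] * sa + p[1] * ca, z = p[2];
    return [x, ce * z - se * y0, se * z + ce * y0];
  }}
  let projected = [];
  function draw() {{
    ctx.clearRect(0, 0, canvas.width, canvas.height);
    const pts = DATA.cells.map(c => {{
      const q = project(c.p);
      return {{cell: c.cell, colour: c.colour, x: q[0], y: q[1], depth: q[2]}};
    }});
    pts.sort((a, b) => a.depth - b.depth);
    const span = Math.max(1e-9, ...pts.map(p => Math.max(Math.abs(p.x), Math.abs(p.y))));
    const s = (Math.min(canvas.width, canvas.height) / 2 - 20) / span;
    projected = pts.map(p => ({{cell: p.cell, colour: p.colour,
      px: canvas.width / 2 + p.x * s, py: canvas.height / 2 - p.y * s}}));
    for (const p of projected) {{
      ctx.beginPath();
      ctx.arc(p.px, p.py, R, 0, 2 * Math.PI);
      ctx.fillStyle = p.colour; ctx.globalAlpha = 0.85; ctx.fill();
      ctx.globalAlpha = 1;
      ctx.lineWidth = selected.has(p.cell) ? 2.5 : 0.5;
      ctx.strokeStyle = selected.has(p.cell) ? "#000" : "#444";
      ctx.stroke();
    }}
  }}
  function highlight(cells) {{
    selected = new Set(cells);
    for (const el2 of tree.querySelectorAll("circle.treecell"))
      el2.classList.toggle("hl", selected.has(el2.dataset.cell));
    draw();
  }}
  let dragging = false, lx = 0, ly = 0;
  canvas.addEventListener("mousedown", e => {{ dragging = true; lx = e.offsetX; ly = e.offsetY; }});
  window.addEventListener("mouseup", () => dragging = false);
  canvas.addEventListener("mousemove", e => {{
    if (dragging) {{
      az += (e.offsetX - lx) * 0.01; el += (e.offsetY - ly) * 0.01;
      lx = e.offsetX; ly = e.offsetY; draw();
    }} else {{
      let best = null, bd = 1e9;
      for (const p of projected) {{
        const d = (p.px - e.offsetX) ** 2 + (p.py - e.offsetY) ** 2;
        if (d < bd) {{ bd = d; best = p; }}
      }}
      if (best && bd < (R + 4) ** 2) hover.textContent = best.cell;
    }}
  }});
  canvas.addEventListener("click", e => {{
    let best = null, bd = 1e9;
    for (const p of projected) {{
      const d = (p.px - e.offsetX) ** 2 + (p.py - e.offsetY) ** 2;
      if (d < bd) {{ bd = d; best = p; }}
    }}
    if (best && bd < (R + 4) ** 2) highlight(DATA.paths[best.cell] || [best.cell]);
  }});
  draw();
}})();
</script>
</body></html>
"""


def render_html(scene: Scene, path: str) -> str:
    """Write a single self-contained interactive HTML file: hoverable cells
    (ID plus descendant counts), click-to-highlight clones linked across the
    tree and 3D panels, and mouse-drag rotation of the 3D view."""
    import json as _json

    layout, width, height, segments, markers, _pts = _scene_geometry(scene)
    tree = scene.joined.tree
    cmap = scene.colour_map()
    frame = scene.joined.cells.frame
    shown = sorted(scene.joined.matched | scene.joined.coords_only)
    centred = frame.loc[shown, ["x", "y", "z"]].to_numpy(dtype=float)
    if len(shown):
        centred = centred - centred.mean(axis=0)
    data = {
        "segments": [[[round(a, 2), round(b, 2)] for a, b in seg]
                     for seg in segments],
        "markers": [
            {"cell": label, "x": round(x, 2), "y": round(y, 2),
             "colour": colour, "collapsed": collapsed,
             "total": total, "on_viewer": on_viewer}
            for label, x, y, colour, collapsed, total, on_viewer in markers
        ],
        "cells": [
            {"cell": cell, "p": [round(float(v), 4) for v in centred[i]],
             "colour": cmap.get(cell, NEUTRAL_COLOUR)}
            for i, cell in enumerate(shown)
        ],
        # clone membership per displayed tree marker, for linked highlighting
        "clones": {label: sorted(clone(tree, label))
                   for label, *_ in markers},
        # root path per positioned cell, to light up its full lineage
        "paths": {cell: _path_labels(tree, cell)
                  for cell in shown if cell in tree},
    }
    html = _HTML_TEMPLATE.format(
        tree_w=int(_TREE_W), w3d=int(_PANEL_3D_W), h=int(height),
        data_json=_json.dumps(data, sort_keys=True),
        sphere_radius=scene.sphere_radius,
        azimuth=scene.azimuth, elevation=scene.elevation,
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(html)
    return path


def _path_labels(tree: LineageTree, cell: str) -> list[str]:
    node = tree.node(cell)
    out = [node.label]
    while node.parent is not None:
        node = node.parent
        out.append(node.label)
    return out[::-1]
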