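# cladeview

Headless linked views of developmental cell lineages: a library + CLI that
joins a **cell-lineage tree** (the genealogy of divisions from a founder
cell) with the **3D positions** of the same cells, computes the clone and
relationship structure an interactive lineage browser exposes, and exports
static (SVG/PNG) and standalone interactive (HTML) linked views.

It is aimed at developmental biologists working with tracked or curated
lineages — e.g. an invariant whole-animal lineage with a partial spatial
atlas, an embryo staged to ~100 cells with cell-fate annotations and marker
expression, or a light-sheet tracking run exported from MaMuT/TrackMate —
who want reproducible, scriptable figures instead of a browser session.

## Data model and computations

Two files define a dataset: a lineage tree (Newick or hierarchical JSON
with `name`/`children`/`length` keys) and a `cell,X,Y,Z` coordinate CSV.
Cell **labels are the join key**; partial overlap is legal and bookkept
(`matched` / `tree_only` / `coords_only`). Branch lengths encode division
timing either *relative* (parent→child distance) or *absolute* (distance of
each node from the root, non-decreasing toward the leaves); `node_times`
and `convert_bl_mode` translate between the two.

On top of the joined data the library computes:

- **clones** — `clone(tree, a)` is the leaf set of the subtree at `a`;
- **depth cuts** — `clones_at_division_depth(tree, k)` partitions cells
  into the clones founded after exactly *k* divisions (root depth 0);
- **time cuts** — `clones_at_time(tree, t)` partitions cells by the edges
  alive at time *t* (edge *p→c* is alive iff `time(p) < t ≤ time(c)`;
  terminated cells persist);
- **lineage relationships** — `relationship_levels(tree, focal)` scores
  every cell by the depth of its most recent common ancestor with the focal
  cell, producing the nested set of clones around it;
- **view edits** — collapse / expand / prune as a non-destructive overlay,
  clone export as JSON, and automatic **branch subsetting** of unresolved
  (polytomous) trees above 500 cells for legible display;
- **overlays** — clone partitions, relationship levels, categorical
  annotations, or one gene's expression as a heatmap, with one colour per
  cell shared by both panels.

Everything is testable offline: `cladeview.synthetic_fixtures` simulates
lineages by a seeded pure-birth process (with optional polytomies), places
cells by a clone-coherent branching random walk, generates annotation and
marker-expression tables, and writes MaMuT-style tracking XML that
round-trips through the importer.

## Worked example

```sh
$ cladeview simulate --out-dir demo --seed 5 --n-leaves 16
wrote dataset (16 cells) to demo

$ cladeview stats demo/tree.nwk --bl-mode relative
{
  "n_cells": 16,
  "n_nodes": 31,
  "max_depth": 6,
  "has_polytomies": false,
  "bl_mode": "relative",
  "final_time": 4.847058267959218
}
```

The simulated lineage has 16 terminal cells in a fully resolved (binary)
tree; the deepest cell sits 6 divisions from the founder, and the last
recorded time point is ≈4.85 time units. Cutting the tree two divisions
down groups the cells into the (up to four) clones that existed then:

```sh
$ cladeview cut demo/tree.nwk --bl-mode relative --depth 2 | head -6
cell,group
c12,c4
c24,c4
c25,c4
c26,c4
c27,c4
```

Each row assigns a terminal cell to the depth-2 ancestor (`c4`, …) that
founded its clone; the CSV uses the same `cell,<category>` dialect as the
annotation reader, so a saved cut can be reloaded as a cell-annotation
file. Finally, a deterministic linked figure (lineage tree left, 3D
projection right, annotation colours shared between panels):

```sh
$ cladeview render --tree demo/tree.nwk --coords demo/coordinates.csv \
    --bl-mode relative --annotations demo/annotations.csv --out scene.svg
wrote scene.svg
```

Use `--format html` for a self-contained interactive page (hover shows a
cell's ID and descendant counts; clicking a tree node highlights its clone
in the 3D panel; dragging rotates the 3D view).

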