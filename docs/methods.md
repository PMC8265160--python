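# Methods

This note records the conventions, models and numerical choices behind
`cladeview`, and what the synthetic data does and does not establish.

## Tree model and label discipline

A lineage tree is a rooted tree of uniquely labelled cells. Labels are the
only key linking the lineage view to the 3D view, so duplicate labels are a
hard error rather than a warning, and unlabelled nodes are auto-named
deterministically (`_n<k>`, breadth-first from the root) so that every node
can be addressed from either panel. The Newick dialect accepts
single-quoted labels (`''` escapes a quote), strips square-bracket
comments, and ignores whitespace outside quotes. The JSON schema is the
common hierarchical form — objects with `name`, optional `children`,
optional `length` — chosen because curated lineages circulate in exactly
this shape; unknown keys are ignored with a warning so annotated files
still load.

## Branch-length conventions and time

Two conventions are supported and declared by the caller, never guessed:
**relative** lengths are parent→child distances, **absolute** lengths are
each node's distance from the root (validated non-decreasing toward the
leaves; a missing root value defaults to 0). `node_times` maps both to a
single timeline. In relative mode the root's own length counts: it is the
founder cell's lifespan before its first division, so a simulated tree's
times line up exactly with its division log. Conversion between modes
preserves node times and round-trips lengths to within 1e-9 (floating
accumulation over prefix sums is the only error source).

## Depth and time cuts

Depth convention: the root has depth 0 and "number of divisions" means
edge count from the root, so a cut at k = 0 returns the root's clone, and
a leaf shallower than k persists as a singleton (a cell that stopped
dividing early still exists later).

Time cuts use a half-open edge rule: edge *p → c* is alive at *t* iff
`time(p) < t ≤ time(c)`, with the root's incoming edge extending back
indefinitely and terminated leaves staying alive at all later times. The
boundary choices make a cell alive at the instant of its own division (not
its daughters), which is what makes the clone count at *t* equal the
simulator's alive-lineage count at every *t*, including exact division
instants and times after the last division. Zero-length edges (collapsed
polytomies) are never alive under this rule, so a polytomy contributes its
children, not a phantom intermediate.

## Lineage relationship

The "degree of lineage relationship" of cell *x* to a focal cell *f* is
formalized as the depth of MRCA(*f*, *x*). This gives the nested-clone
picture directly: the cells at level ≥ L are exactly the clone of *f*'s
depth-L ancestor. It is computed in one pass down the focal cell's root
path (each ancestor stamps its clone), which is O(total clone sizes)
rather than quadratic.

## Branch subsetting

Display reduction of unresolved trees activates only when both conditions
hold: more than `max_cells` cells (default 500) *and* at least one
polytomy; a fully resolved tree is never reduced, however large. The
reduction keeps the first *k* label-sorted children at every polytomy,
with *k* the largest uniform value bringing the displayed leaf count to at
most `max_cells`, floored at 2 children per polytomy (so the displayed
count can exceed the cap only when the 2-per-polytomy floor forces it).
Label-sorted prefixes make the result deterministic and seedless; the
report lists hidden branch counts per polytomy so nothing disappears
silently.

## Joins and the two panels

`join` intersects tree leaves with coordinate labels; partial coverage is
legal in both directions (a warning records the three set sizes), and only
an empty intersection is an error. Cells present in the tree but not
positioned are drawn only in the lineage panel and counted in a node's
`total_descendants` but not `on_viewer_descendants`; a leaf counts itself,
so hover numbers equal clone sizes. Coordinate-only cells appear in the 3D
panel in the neutral colour.

## Rendering

Static export is a pure function of the `Scene`: floats are written at
fixed precision, there are no timestamps or random ids, so identical
scenes give byte-identical SVG. The 3D panel of a static image is an
orthographic projection at a configurable azimuth/elevation with painter's
ordering along the view axis; free rotation lives only in the HTML export,
which embeds all data and script inline in one file. Cladogram layout puts
internal nodes at their depth and all leaf slots at the deepest displayed
depth; branch-length layout uses node times on the x axis. Categorical
overlays draw from a 12-colour maximally distinct palette and cycle with a
warning beyond 12 groups; expression and relationship overlays use a
sequential perceptually ordered scale (viridis anchor points interpolated
in RGB) with the numeric range recorded in the legend. PNG export draws
the same geometry through matplotlib's Agg backend and is not guaranteed
byte-stable (font rasterization), which is why determinism is specified at
the SVG level.

## Tracking-XML import

The importer reads the TrackMate/MaMuT single-file schema (spots with
`ID`, optional `name`, `FRAME`, positions; edges source→target). Chains of
single-successor spots collapse into one tree edge whose relative length
is the frame span; 2+ successors make a division node, 0 make a leaf.
Cells are labelled by the spot `name` when present, else the numeric id.
Coordinates are taken at each leaf's last spot, consistent with a 3D view
showing the final time point only. Dangling edge references, cycles, a
spot with two mothers, and multiple disconnected tracks are all errors
(the single-lineage contract keeps the join unambiguous).

## Synthetic data: what it emulates and what it does not

`simulate_lineage` is a pure-birth process: every lineage waits an
exponential (default rate 1) or fixed time and divides in two until the
target cell count; leaves then persist one mean waiting time so terminal
branches have positive length. Polytomies are produced by letting a
daughter divide instantly with probability `polytomy_rate` and collapsing
the zero-length edge — the same unresolved-order structure curated
lineages show. The division log (sorted division times) is the ground
truth for time cuts.

`walk_positions` places cells by a branching random walk: each daughter
adds one displacement of scale `spatial_step` blending a heritable drift
direction (weight `coherence`) with isotropic Gaussian noise. Sibling
drifts are independent, so sister clones separate while each clone stays
compact; at coherence 0.9 the mean intra-clone pairwise distance of
depth-2 clones falls below the inter-clone distance in ≥ 18 of 20 seeded
200-cell runs. This emulates clonally contiguous territories, not any
biophysical morphogenesis — passing tests say the bookkeeping and geometry
pipeline is correct, not that real embryos look like the walk.

Annotations and expression mark chosen depth-2 clades: a fate label per
clade, and one marker gene per clade drawn log-normally (σ = 0.5) around
mean 10 inside and 0.1 outside, plus unit-mean background genes. Defaults
(64–110 cells per fixture, 2–3 marker clades, 5–8 genes) are sized like a
gastrula-stage embryo staged to ~100 cells.

The packaged `fixture_suite` covers the supported feature matrix: Newick +
relative lengths + annotations with *partial* coordinates (a whole-animal
lineage joined to a partial spatial atlas, 64 of 100 cells positioned);
Newick + no lengths + annotations + expression; JSON + absolute lengths
(with a Newick twin); JSON topology only (with polytomies).

## Problem sizes

Oracle-equivalence checks run on 1000 random trees (mostly ≤ 40 leaves,
periodically up to 200, mixed polytomy rates and all three branch-length
modes) against networkx-based brute-force traversals; partition and
nested-clone laws on 300 trees; simulator ground truth on 50 runs × 20
time points; round trips on ~80 trees plus 25 tracking-XML fixtures. These
sizes exercise every code path (polytomies, unary chains, partial joins)
while keeping the full suite fast enough to run on every change.

## Known limitations

- One lineage per dataset; multi-embryo or multi-track files must be split
  upstream.
- No NEXUS/PhyloXML/NHX, no rerooting, no topology editing beyond
  collapse/prune overlays.
- The 3D panel shows the final time point only; positions at intermediate
  times are not modelled even when the tracking XML contains them.
- Static SVG cannot rotate; the azimuth/elevation are part of the scene.
- Expression files are dense cell × gene CSV; sparse matrices and count
  QC belong upstream.
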