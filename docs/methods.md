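# Methods

This note records the geometric model the package implements, the
parameters that matter, the algorithmic choices made where the design was
genuinely open, and what the synthetic data does and does not exercise.

## Coordinate system and grid

All drawing geometry lives on an integer grid with step **10 units**
(`GRID_STEP`), screen convention: x grows rightward, y grows downward,
origin top-left.  Every pad and corner produced by the layout and repair
code is grid-snapped; hand-built or perturbed trees may be off-grid until
a tool touches them.  Rectangles are half-open, `[x0, x1) × [y0, y1)`,
which gives every boundary point a unique owner in containment tests.
Node footprints: a gene is a 20-unit-tall bar at least 80 wide (8 units
per label character, rounded up to the grid); other node kinds (box,
bubble, intercell, slash) are 20 × 20.  These dimensions are a drawing
convention, not data: they were fixed once for visual proportion.

## Link trees and well-formedness

A link tree carries every outbound link of one source: a rooted tree of
corner points whose edges are the drawn segments, with one leaf pad per
(target, sign) pair — leaves are keyed by the pair, not by the target
alone, because a source may both promote and repress the same target and
each such link needs its own pad.  A tree is *well-formed* when no two
distinct segments share a collinear run of positive length and no two
meet except at a point that is an endpoint of both and a shared tree
node.  T-junctions and coincident corners of unrelated branches are
counted as problems: both make the clicked point ambiguous.  The audit
(`is_well_formed`) is a brute-force all-pairs check; tree sizes make
anything cleverer pointless.

A *180-degree turn* is a property of a root-to-leaf path: two
path-adjacent segments whose away-directions from the shared corner are
equal (the drawn path folds straight back on itself).  Two sibling
branches leaving a corner in the same direction are merely untidy
geometry — the repair tool's business, not a fold.

## Stacked layout

Parameters (grid units): `max_row_size` 20, `row_gap` 40, `track_pitch`
10, `spine_pitch` 10, `node_gap` 20.  The strategy:

1. **Ordering** (`order_targets_by_source`): sources (out-degree ≥ 1)
   first in id order; pure targets after, grouped by input signature (the
   sorted set of sources feeding them), groups in signature order.  A
   non-gene node feeding exactly one gene is pulled adjacent to that gene
   so the pair shares a row — genes stay first-class citizens.
2. **Rows**: row-major fill, at most `max_row_size` per row; a break that
   would strand a feeder non-gene from its gene moves one slot earlier.
3. **Placement**: above each row a *track band* with one 10-unit track
   per source that needs the row (placed in it with outputs, or targeting
   it); left of the block a *spine band* with one 10-unit column per
   source.  Tracks and columns are assigned in global source-id order
   (topmost/leftmost first) — the ordering is arbitrary but fixed, which
   is what makes the output reproducible byte-for-byte.  Node placements
   are widened beyond the footprint when a target needs more landing-pad
   slots (one grid slot per inbound (source, sign), skipping the node's
   own launch slot so an ascent never shares x with a drop).
4. **Routing**: each tree ascends from the launch pad (top-center of the
   source) into its own track, runs horizontally to same-row pads and to
   its spine column, travels the spine vertically, re-enters each target
   row on its own track there, and lands with a single vertical drop onto
   the target's top edge.  Distinct sources never share a track line or a
   spine column, so trees can only cross perpendicularly — crossings are
   visually unambiguous and permitted; collinear sharing between trees
   cannot occur by construction.

No attempt is made to minimize total link ink or crossings; the layout is
intentionally canonical and predictable.  The spine sits left of the
whole block (one spine for all rows, not one per row).

## Orthogonalization ("minimize shifts")

For each non-orthogonal segment, candidates in cost order: the two
single-elbow splits (cost 0, tie broken horizontal-first), then — for a
movable interior child corner — snapping the corner onto the nearer axis
(cost = L1 displacement of the moved corner).  A candidate is discarded
if a new segment crosses a node-footprint interior (touching a boundary
is fine), collinearly rides another tree's segment, or folds back
180° along the path.  When every simple candidate is blocked, the segment
is replaced by a multi-corner orthogonal polyline found by an A* router
over the grid (same rejection rules, turn-penalized to prefer straight
runs); when even that fails the tool raises a no-solution error naming
the segment, leaving the user to add guiding corners.  Pads never move;
segments that are already orthogonal are never re-routed (the tool does
no de novo layout), so a perturbation that leaves an orthogonal segment
crossing a node is outside its contract — the guarantee is that it
introduces no crossing of its own.  The exact objective of the original
interactive tool is unpublished; the L1 cost and these tie-breaks are
this package's own definition, so geometric equality with any other
implementation is not claimed.

## Overlap repair

The repair tool keeps the root, the leaf pads and the target set and
discards the malformed interior.  Leaves are re-routed in sorted key
order by a turn-penalized A* over the grid graph, multi-sourced from
every point of the already-routed tree; a path attaches wherever it first
meets the tree, which merges shared prefixes into trunk segments.  The
search never re-enters an existing tree point, which structurally rules
out self-crossings and collinear self-overlaps at grid resolution, and
refuses moves that ride foreign segments or enter footprint interiors.
The routing region is the bounding box of root and pads inflated by 100
units, retried at 400 before reporting the unreachable targets.  Obstacle
interiors are tested strictly, so geometry thinner than one grid step
could in principle be stepped over; all footprints this package produces
are at least 20 units thick in each axis.

## Overlay-driven layout

Each module's members are laid out by the stacked strategy on the induced
sub-network (landing-pad slots sized against the *full* model so
inter-module inputs have somewhere to land).  Boxes are then packed by
order-preserving coordinate compaction: sorted by original center-x, they
receive disjoint x-extents left-to-right with a 60-unit channel gap, and
likewise for y — strict center orderings are preserved in both axes by
construction, boxes are disjoint because the x-extents alone already are,
and no general packing problem is solved.  The acknowledged cost is
boxes and total canvas larger than strictly necessary.  Center order (not
edge order) is the preserved quantity; module labels are not
repositioned.

Inter-module node links are routed in three attached legs: source tree →
exit portal just outside the source box, portal → entry portal just
outside the target box (box interiors blocked; per-source lane offsets
spread portals so different sources' runs get separate lines, with the
router's foreign-segment avoidance as the backstop), and entry portal →
landing pad.  Exit and entry sides are read from the drawn module link's
first and last waypoint segments, falling back to the dominant axis
between box centers.  Nodes assigned to no module are laid out in a
trailing `unassigned` pseudo-module and excluded from the returned
overlay.  Validation blocks on missing module links, crooked
(non-orthogonal) module links, unknown members and double assignment;
unassigned nodes are a warning.

Geometry is stored once per layout; submodels of the hierarchy do not
carry geometry of their own in this version.

## Rendering, hit-testing, export

Draw layers, bottom to top: module underlays, links, nodes, labels,
overlay boxes (module frames and module links), selection.  Link strokes
are 4 units wide; a click within half the stroke width of a center-line
hits the tree.  Promotion ends in a filled arrowhead, repression in a
perpendicular bar, neutral links end bare.  Selection variants (orange
outlines, thickened strokes) are pre-generated into every node and tree
group.  Each group's intersection bounds are per-shape boxes padded so
the boundary-inclusive precise tests can never hit outside them — the
bounds are a sound pre-filter, the precise shape test decides.  Ties
within a layer go to the group with the smallest total bounds area.  The
JSON scene document (schema in `docs/schema.md`, checked by a validator
shipped in the package) serializes with sorted keys and integer
coordinates, so equal scenes give byte-equal documents; the SVG writer
emits exactly one element per primitive shape in layer order, with color
tokens resolved through a fixed palette.

## Synthetic data

The generator emulates a simulated regulatory network with a control tier
and a target tier: `n_control` = 6 control genes wired to each other
sparsely (edge probability 0.3), `n_targets` = 60 sink genes each wired
to exactly one of `n_signatures` = 6 sampled input signatures (distinct
control subsets of size 1–3), link signs drawn 0.7/0.3
promote/repress.  These defaults are a desk-scale working size chosen
once; the structure (controls with outputs, targets grouped by input
combination) is the point, the counts are not.  The first `n_signatures`
targets take one signature each so no sampled signature is empty; a
control left without outputs receives one control→control edge.  The
matching overlay splits controls into two boxes and makes one box per
signature, with module links covering every inter-module node link — so
it validates clean by construction.

`perturb_tree` simulates a user quickly dragging geometry: corner drags
displace an interior corner by 10–30 units diagonally (both components
non-zero), segment drags shift a whole interior segment perpendicular to
itself.  Root and pads never move, topology is preserved, and drags that
would drop a corner strictly inside a given footprint are redrawn —
users drop corners into whitespace.  What this does *not* emulate:
hand-drawn networks with arbitrary off-grid geometry, node kinds beyond
genes, real regulatory-network degree distributions, or adversarial
obstacle mazes.  Passing the suites shows the tools are correct and
total on drag-style malformations of realistic layouts, not that every
conceivable malformed tree is repairable — blocked targets are reported,
not silently dropped.

## Known limitations

- Only the One-Box module type exists; multi-rectangle and auto-member
  modules are out of scope, as are region/time-course semantics.
- The overlay box packing trades canvas area for order preservation;
  no compaction pass is attempted afterwards.
- The router works at grid resolution; obstacles must be at least one
  grid step thick to be reliable walls.
- SVG output maps style tokens to a fixed palette; theming means editing
  the palette.
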