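# grnlayout

Geometry core for drawing gene regulatory network (GRN) diagrams:
orthogonal hyperedge routing, automatic stacked and overlay-driven layout,
link-tree repair tools, and a platform-neutral rendering export with
hit-testing.

## The problem

GRN diagrams are wiring diagrams: genes drawn as wide bars, with signed
regulatory links (promote / repress / neutral) running between them as
axis-aligned "circuit traces".  Rather than drawing one independent edge
per interaction, all outbound links of a source gene share a single
routing structure — a **link tree** (a rooted orthogonal tree whose root
is the source's launch pad and whose leaves are landing pads on each
target).  Shared trunk segments make large fan-outs compact and readable,
but they also make geometry correctness matter: a tree whose segments
collinearly overlap or cross itself *looks* fine while making every mouse
click on the shared run ambiguous.

This package implements the machinery a GRN drawing tool needs around
that representation, for people building or scripting network figures:

- **Data model** — genes and auxiliary node kinds, signed links, and a
  model hierarchy in which every child model may contain only a subset of
  its parent's elements (`core_model`).
- **Grid geometry** — integer-grid points/segments/rectangles, the link
  tree structure, overlap classification, and the well-formedness audit
  (`grid_geometry`).
- **Stacked layout** — nodes in bounded rows; every horizontal run lives
  in a reserved track band above its row (one track per source), and
  every inter-row vertical lives in the source's own column of a shared
  spine band down the left of the block.  Deliberately not ink-optimal:
  the contract is total predictability (`stacked_layout`).
- **Drawing tools** — *orthogonalize* (split and shift roughed-in
  diagonal segments onto the axes, refusing candidates that cross nodes,
  ride foreign trees, or fold back 180°) and *repair* (re-route a
  malformed tree from its pads over a grid graph, merging shared
  prefixes back into trunks) (`link_tools`).
- **Overlays and overlay-driven layout** — named One-Box modules over
  node sets plus directed module links; the layout stacks each module
  internally, repositions boxes preserving the relative orderings of the
  original box centers, and routes inter-module node links through the
  channels between boxes following the drawn module links' exit/entry
  sides (`overlay_layout`).
- **Rendering export** — every element renders to a CacheGroup of
  primitive shapes with a pre-generated selection variant and
  intersection bounds, bucketed into ordered draw layers; serialize to a
  documented JSON scene format or SVG 1.1, and answer point hit-tests
  (`render_export`).
- **Synthetic networks** — a seeded generator of control/target GRNs
  (targets grouped by their combination of control-gene inputs), matching
  overlays, and simulated drag perturbations for exercising the tools
  (`synth_grn`).
- **CLI** — `grnlayout synth | layout | fix-ortho | repair |
  validate-overlay | render | run-use-case` (`cli`).

Networks are read and written as Cytoscape SIF (`source relation
target...`, tab-delimited); overlays as a small YAML document; layouts
and scenes as JSON (see `docs/schema.md`).

## Worked example

```python
import grnlayout as gl

model = gl.generate_grn(gl.SynthParams(seed=42))
print(model)
# GrnModel('synth-grn-seed42', 66 nodes, 114 links)

layout = gl.stacked_layout(model, gl.StackedParams(max_row_size=20))
print([len(r) for r in layout.meta["rows"]])
# [20, 20, 20, 6]          <- rows capped at the requested 20 nodes

tree = layout.trees["C1"]
print(len(gl.tree_targets(tree)), gl.is_well_formed(tree))
# 2 []                      <- C1's tree reaches its 2 targets, no
#                              overlapping/crossing segments

overlay = gl.generate_overlay_from_signatures(model)
olayout, new_overlay = gl.overlay_driven_layout(model, overlay)
print([m.name for m in new_overlay.modules])
# ['controls-1', 'controls-2', 'targets-1', ..., 'targets-6']
#   two control-gene boxes + one box per distinct input combination

scene = gl.render_model(model, olayout, new_overlay)
print(sum(len(g.shapes) for g in scene.groups()))
# 605                       <- primitive shapes across all draw layers
print(gl.hit_test(scene, gl.GridPoint(*map(int, olayout.placements["C1"].center))))
# C1                        <- clicking the C1 bar resolves to C1
svg = gl.write_svg(scene)  # one SVG element per primitive shape
```

The same workflow from the shell:

```sh
grnlayout synth --seed 42 -o net.sif --overlay overlay.yaml
grnlayout run-use-case net.sif --overlay overlay.yaml --out-dir out/
# ok: 66 nodes, 6 trees, 8 modules
```

`out/` then holds `layout.json`, `scene.json` and `out.svg`.  A missing
module link or a crooked (non-orthogonal) module link makes
`run-use-case` exit with status 2 and list each problem.

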