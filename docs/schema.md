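# File formats

All files are UTF-8 text.

## SIF networks

Cytoscape Simple Interaction Format: one record per line,
`source<TAB>relation<TAB>target[<TAB>target...]`; a line with a single
token declares an isolated node.  Tabs are the delimiter when present,
otherwise any whitespace.  Relation tokens map to link signs through a
configurable dialect; the default is

| token      | sign    |
|------------|---------|
| `positive` | promote |
| `negative` | repress |
| anything else | neutral |

`read_sif(..., strict_relations=True)` turns unknown tokens into errors
listing the accepted vocabulary.  Duplicate lines are deduplicated with a
warning.  `write_sif` emits links sorted by (source, target, sign) and
then isolated nodes, so equal models give byte-equal files.

## Overlay documents (YAML, `schema_version: 1`)

```yaml
schema_version: 1
name: signature-modules
intensity: 0.15            # [0, 1], presentation only
modules:
  - name: controls-1
    members: [C1, C2, C3]
    box: [x0, y0, x1, y1]  # optional provisional box, grid units
module_links:
  - source: controls-1
    target: targets-2
    sign: positive         # module links are promoting
    waypoints: [[x, y], [x, y], ...]   # drawn orthogonal polyline
```

Module names must be unique, member lists non-empty, link endpoints must
name declared modules.  Membership against a concrete network is checked
at use time by `validate_overlay`.

## Layout documents (JSON, `schema_version: 1`)

Top level: `schema_version`, `model` (`name`, `nodes` with
`id`/`label`/`kind`, `links` as `[source, relation-token, target]`),
`bounds` `[x0, y0, x1, y1]`, `placements` (node id → rectangle), and
`trees` (source id → link tree: `root` node id, `points` (tree node id →
`[x, y]`), `parent` (child id → parent id), `leaves` as
`[[target, relation-token, tree-node-id], ...]`).  Serialization sorts
keys and uses integer coordinates: deterministic bytes.

## Scene documents (JSON, `schema_version: 1`)

```
{
  "schema_version": 1,
  "grid_step": 10,
  "bounds": [x0, y0, x1, y1],
  "layers": [
    {"name": "underlay_modules", "ordinal": 0, "groups": [
      {"id": "module:controls-1",
       "shapes": [...],
       "selected_shapes": [...],
       "bounds": [[x0, y0, x1, y1], ...]},
      ...
    ]},
    ... one entry per draw layer, ascending ordinal ...
  ]
}
```

Layer ordinals: 0 `underlay_modules`, 1 `links`, 2 `nodes`, 3 `labels`,
4 `overlay_boxes`, 5 `selection`.  Group ids: node id, `link:<source>`,
`module:<name>`, `modlink:<a>-><b>`.

Each shape is `{"type": ..., "geometry": {...}, "style": {...}}` with
geometry keys by type:

| type      | geometry keys              |
|-----------|----------------------------|
| `line`    | `x1, y1, x2, y2`           |
| `rect`    | `x, y, w, h`               |
| `ellipse` | `cx, cy, rx, ry`           |
| `path`    | `points` (list of `[x, y]`), `closed` |
| `text`    | `x, y, text`               |

Style entries are tokens (`stroke`, `fill`, `width`, `dash`, `opacity`,
`size`); renderers resolve color tokens themselves (the bundled SVG
writer uses a fixed palette).  A group's `bounds` rectangles are a
superset of every shape's extent and drive hit-test pre-filtering.

`grnlayout.validate_scene_doc(doc)` checks a parsed document against this
schema and returns a list of problems (empty = valid).
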