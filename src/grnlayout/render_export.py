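"""Platform-neutral rendering: primitive shape streams, draw layers,
hit-testing, JSON serialization and SVG output.

Every drawable element (node, link tree, module box, module link) renders
itself into a *CacheGroup*: an ordered stream of low-level primitive
shapes, a pre-generated "selected" variant of those shapes, and a list of
coarse intersection bounds used as a hit-test pre-filter.  Groups are
bucketed into strictly ordered draw layers (module underlays below links
below nodes below labels...), which fixes paint order for any renderer.
The JSON document is the wire format a remote client would consume; the
SVG writer is the local equivalent of such a client.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core_model import GrnModel, NodeKind, Sign
from .grid_geometry import GRID_STEP, GridPoint, LinkTree, Rect, Segment
from .stacked_layout import Layout

SCHEMA_VERSION = 1

#: stroke width of link segments; a click within half this of a segment
#: center-line counts as a hit
LINK_WIDTH = 4

_ARROW = 8   # arrowhead glyph size
_BAR = 10    # repression bar length


class DrawLayer(enum.IntEnum):
    UNDERLAY_MODULES = 0
    LINKS = 1
    NODES = 2
    LABELS = 3
    OVERLAY_BOXES = 4
    SELECTION = 5


@dataclass(frozen=True)
class PrimitiveShape:
    """One low-level drawable: type, per-type geometry, style tokens."""

    type: str                 # line | rect | ellipse | path | text
    geometry: tuple           # per-type, see _GEOMETRY_FIELDS
    style: tuple = ()         # sorted (key, value) pairs

    @staticmethod
    def line(x1, y1, x2, y2, **style) -> "PrimitiveShape":
        return PrimitiveShape("line", tuple(sorted((("x1", x1), ("y1", y1),
                                                    ("x2", x2), ("y2", y2)))),
                              _style(style))

    @staticmethod
    def rect(x, y, w, h, **style) -> "PrimitiveShape":
        return PrimitiveShape("rect", (("h", h), ("w", w), ("x", x), ("y", y)),
                              _style(style))

    @staticmethod
    def ellipse(cx, cy, rx, ry, **style) -> "PrimitiveShape":
        return PrimitiveShape("ellipse", (("cx", cx), ("cy", cy),
                                          ("rx", rx), ("ry", ry)),
                              _style(style))

    @staticmethod
    def path(points: Iterable[tuple], closed: bool = False,
             **style) -> "PrimitiveShape":
        pts = tuple((int(x), int(y)) for x, y in points)
        return PrimitiveShape("path", (("closed", closed), ("points", pts)),
                              _style(style))

    @staticmethod
    def text(x, y, text: str, **style) -> "PrimitiveShape":
        return PrimitiveShape("text", (("text", text), ("x", x), ("y", y)),
                              _style(style))

    def geom(self) -> dict:
        return dict(self.geometry)


def _style(kw: dict) -> tuple:
    return tuple(sorted(kw.items()))


@dataclass(frozen=True)
class CacheGroup:
    """Per-element shape bundle with pre-generated selection variant and
    intersection bounds (a superset of every shape's extent)."""

    element_id: str
    layer: DrawLayer
    shapes: tuple[PrimitiveShape, ...]
    selected_shapes: tuple[PrimitiveShape, ...] = ()
    bounds: tuple[Rect, ...] = ()


@dataclass
class Scene:
    """Ordered CacheGroups per draw layer plus document metadata."""

    layers: dict[DrawLayer, list[CacheGroup]]
    bounds: Rect
    grid_step: int = GRID_STEP

    def groups(self) -> list[CacheGroup]:
        out = []
        for layer in sorted(self.layers):
            out.extend(self.layers[layer])
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Scene):
            return NotImplemented
        return (self.bounds == other.bounds
                and self.grid_step == other.grid_step
                and {k: list(v) for k, v in self.layers.items()}
                == {k: list(v) for k, v in other.layers.items()})


class UnplacedElementError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Shape generation


def _shape_bounds(shape: PrimitiveShape) -> Rect:
    g = shape.geom()
    if shape.type == "line":
        half = dict(shape.style).get("width", LINK_WIDTH) // 2 + 1
        x0, x1 = sorted((g["x1"], g["x2"]))
        y0, y1 = sorted((g["y1"], g["y2"]))
        return Rect(x0 - half, y0 - half, x1 + half, y1 + half)
    if shape.type == "rect":
        return Rect(g["x"], g["y"], g["x"] + g["w"], g["y"] + g["h"])
    if shape.type == "ellipse":
        # +1: the precise test includes the boundary, the half-open box
        # would exclude its right/bottom extremes
        return Rect(g["cx"] - g["rx"] - 1, g["cy"] - g["ry"] - 1,
                    g["cx"] + g["rx"] + 1, g["cy"] + g["ry"] + 1)
    if shape.type == "path":
        xs = [p[0] for p in g["points"]]
        ys = [p[1] for p in g["points"]]
        pad = 1 if g["closed"] else LINK_WIDTH // 2 + 1
        return Rect(min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)
    if shape.type == "text":
        w, h = _text_extent(g["text"])
        return Rect(g["x"], g["y"] - h, g["x"] + w, g["y"])
    raise ValueError(f"unknown shape type {shape.type!r}")


def _text_extent(text: str) -> tuple[int, int]:
    """Nominal text box: 8 units per character, 14 tall (platform renderers
    re-measure; these drive hit bounds only)."""
    return 8 * len(text), 14


def _render_node(node, rect: Rect) -> CacheGroup:
    if node.kind is NodeKind.GENE:
        shapes = [PrimitiveShape.rect(rect.x0, rect.y0, rect.width,
                                      rect.height, fill="gene",
                                      stroke="outline", width=1),
                  PrimitiveShape.line(rect.x0, rect.y1, rect.x1, rect.y1,
                                      stroke="gene-baseline", width=2)]
    elif node.kind is NodeKind.BUBBLE:
        cx, cy = (rect.x0 + rect.x1) // 2, (rect.y0 + rect.y1) // 2
        shapes = [PrimitiveShape.ellipse(cx, cy, rect.width // 2,
                                         rect.height // 2, fill="bubble",
                                         stroke="outline", width=1)]
    elif node.kind is NodeKind.SLASH:
        shapes = [PrimitiveShape.line(rect.x0, rect.y1, rect.x1, rect.y0,
                                      stroke="slash", width=2)]
    else:  # box / intercell
        shapes = [PrimitiveShape.rect(rect.x0, rect.y0, rect.width,
                                      rect.height, fill=node.kind.value,
                                      stroke="outline", width=1)]
    sel = rect.inflate(4)
    selected = [PrimitiveShape.rect(sel.x0, sel.y0, sel.width, sel.height,
                                    stroke="selection", fill="none", width=2)]
    return CacheGroup(element_id=node.id, layer=DrawLayer.NODES,
                      shapes=tuple(shapes), selected_shapes=tuple(selected),
                      bounds=(rect,) + tuple(_shape_bounds(s) for s in shapes))


def _render_label(node, rect: Rect) -> CacheGroup:
    w, h = _text_extent(node.label)
    x = (rect.x0 + rect.x1 - w) // 2
    y = rect.y0 - 4
    shape = PrimitiveShape.text(x, y, node.label, fill="label", size=12)
    return CacheGroup(element_id=node.id, layer=DrawLayer.LABELS,
                      shapes=(shape,), selected_shapes=(),
                      bounds=(_shape_bounds(shape),))


_SIGN_STROKE = {Sign.PROMOTE: "promote", Sign.REPRESS: "repress",
                Sign.NEUTRAL: "neutral"}


def _leaf_glyph(tree: LinkTree, nid: int, sign: Sign) -> list[PrimitiveShape]:
    """Terminal glyph at a landing pad: arrowhead for promotion, a
    perpendicular bar for repression, nothing for neutral."""
    pad = tree.points[nid]
    parent = tree.parent.get(nid)
    if parent is None:
        return []
    prev = tree.points[parent]
    dx, dy = 0, 1  # default: arriving downward
    if prev != pad:
        d = Segment(prev, pad).direction
        if d != (0, 0):
            dx, dy = d
    if sign is Sign.PROMOTE:
        # triangle pointing along (dx, dy)
        px, py = -dy, dx  # perpendicular
        tip = (pad.x, pad.y)
        base1 = (pad.x - dx * _ARROW + px * _ARROW // 2,
                 pad.y - dy * _ARROW + py * _ARROW // 2)
        base2 = (pad.x - dx * _ARROW - px * _ARROW // 2,
                 pad.y - dy * _ARROW - py * _ARROW // 2)
        return [PrimitiveShape.path([tip, base1, base2], closed=True,
                                    fill="promote")]
    if sign is Sign.REPRESS:
        px, py = -dy, dx
        return [PrimitiveShape.line(pad.x - px * _BAR // 2,
                                    pad.y - py * _BAR // 2,
                                    pad.x + px * _BAR // 2,
                                    pad.y + py * _BAR // 2,
                                    stroke="repress", width=3)]
    return []


def _render_tree(tree: LinkTree) -> CacheGroup:
    signs = {sign for (_t, sign) in tree.leaf_ids}
    stroke = _SIGN_STROKE[min(signs, key=int)] if signs else "neutral"
    shapes: list[PrimitiveShape] = []
    selected: list[PrimitiveShape] = []
    bounds: list[Rect] = []
    for seg in tree.segments():
        shapes.append(PrimitiveShape.line(seg.a.x, seg.a.y, seg.b.x, seg.b.y,
                                          stroke=stroke, width=LINK_WIDTH))
        selected.append(PrimitiveShape.line(seg.a.x, seg.a.y,
                                            seg.b.x, seg.b.y,
                                            stroke="selection",
                                            width=LINK_WIDTH + 4))
        bounds.append(_shape_bounds(shapes[-1]))
    for (target, sign), nid in sorted(tree.leaf_ids.items(),
                                      key=lambda kv: (kv[0][0],
                                                      int(kv[0][1]))):
        for glyph in _leaf_glyph(tree, nid, sign):
            shapes.append(glyph)
            bounds.append(_shape_bounds(glyph))
    return CacheGroup(element_id=f"link:{tree.source}", layer=DrawLayer.LINKS,
                      shapes=tuple(shapes), selected_shapes=tuple(selected),
                      bounds=tuple(bounds))


def _render_module_box(name: str, box: Rect, intensity: float) -> CacheGroup:
    shapes = [
        PrimitiveShape.rect(box.x0, box.y0, box.width, box.height,
                            fill="module", opacity=round(intensity, 3),
                            stroke="module-border", width=1),
        PrimitiveShape.text(box.x0 + 4, box.y0 + 16, name,
                            fill="module-label", size=12),
    ]
    return CacheGroup(element_id=f"module:{name}",
                      layer=DrawLayer.UNDERLAY_MODULES,
                      shapes=tuple(shapes),
                      selected_shapes=(PrimitiveShape.rect(
                          box.x0 - 2, box.y0 - 2, box.width + 4,
                          box.height + 4, stroke="selection", fill="none",
                          width=2),),
                      bounds=(box,) + tuple(_shape_bounds(s) for s in shapes))


def _render_module_link(link) -> CacheGroup:
    shapes: list[PrimitiveShape] = []
    bounds: list[Rect] = []
    wps = list(link.waypoints)
    for a, b in zip(wps, wps[1:]):
        if a == b:
            continue
        shapes.append(PrimitiveShape.line(a.x, a.y, b.x, b.y,
                                          stroke="module-link", width=6))
        bounds.append(_shape_bounds(shapes[-1]))
    if len(wps) >= 2 and wps[-1] != wps[-2]:
        d = Segment(wps[-2], wps[-1]).direction
        px, py = -d[1], d[0]
        tip = (wps[-1].x, wps[-1].y)
        b1 = (tip[0] - d[0] * _ARROW + px * _ARROW // 2,
              tip[1] - d[1] * _ARROW + py * _ARROW // 2)
        b2 = (tip[0] - d[0] * _ARROW - px * _ARROW // 2,
              tip[1] - d[1] * _ARROW - py * _ARROW // 2)
        shapes.append(PrimitiveShape.path([tip, b1, b2], closed=True,
                                          fill="module-link"))
        bounds.append(_shape_bounds(shapes[-1]))
    return CacheGroup(element_id=f"modlink:{link.source}->{link.target}",
                      layer=DrawLayer.OVERLAY_BOXES,
                      shapes=tuple(shapes), selected_shapes=(),
                      bounds=tuple(bounds))


def render_model(model: GrnModel, layout: Layout,
                 overlay=None) -> Scene:
    """Render a laid-out model into a scene graph.

    One CacheGroup per node (plus one for its label), per link tree, and —
    when an overlay is given — per module box and module link, with
    selection variants pre-generated for nodes and trees.
    """
    layers: dict[DrawLayer, list[CacheGroup]] = {layer: [] for layer in DrawLayer}
    for nid in sorted(model.nodes):
        if nid not in layout.placements:
            raise UnplacedElementError(nid)
        node = model.nodes[nid]
        rect = layout.placements[nid]
        layers[DrawLayer.NODES].append(_render_node(node, rect))
        layers[DrawLayer.LABELS].append(_render_label(node, rect))
    for src in sorted(layout.trees):
        layers[DrawLayer.LINKS].append(_render_tree(layout.trees[src]))
    if overlay is not None:
        boxes = {}
        for m in overlay.modules:
            if m.box is None:
                raise UnplacedElementError(f"module {m.name} has no box")
            boxes[m.name] = m.box
        for name in sorted(boxes):
            layers[DrawLayer.UNDERLAY_MODULES].append(
                _render_module_box(name, boxes[name], overlay.intensity))
        for link in sorted(overlay.module_links,
                           key=lambda l: (l.source, l.target)):
            layers[DrawLayer.OVERLAY_BOXES].append(_render_module_link(link))
    all_bounds = [b for groups in layers.values()
                  for g in groups for b in g.bounds]
    bounds = Rect.bounding(all_bounds) if all_bounds else Rect(0, 0, 0, 0)
    return Scene(layers=layers, bounds=bounds)


# ---------------------------------------------------------------------------
# Hit testing


def _dist_point_segment(px, py, x1, y1, x2, y2) -> float:
    vx, vy = x2 - x1, y2 - y1
    wx, wy = px - x1, py - y1
    vv = vx * vx + vy * vy
    if vv == 0:
        return math.hypot(wx, wy)
    t = max(0.0, min(1.0, (wx * vx + wy * vy) / vv))
    return math.hypot(px - (x1 + t * vx), py - (y1 + t * vy))


def _point_in_polygon(px, py, pts) -> bool:
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    # boundary counts as inside
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if _dist_point_segment(px, py, x1, y1, x2, y2) < 1e-9:
            return True
    return inside


def shape_hit(shape: PrimitiveShape, p: GridPoint) -> bool:
    """Precise containment test of a point against one primitive."""
    g = shape.geom()
    if shape.type == "line":
        half = dict(shape.style).get("width", LINK_WIDTH) / 2.0
        return _dist_point_segment(p.x, p.y, g["x1"], g["y1"],
                                   g["x2"], g["y2"]) <= half
    if shape.type == "rect":
        return Rect(g["x"], g["y"], g["x"] + g["w"],
                    g["y"] + g["h"]).contains(p)
    if shape.type == "ellipse":
        if g["rx"] == 0 or g["ry"] == 0:
            return False
        nx = (p.x - g["cx"]) / g["rx"]
        ny = (p.y - g["cy"]) / g["ry"]
        return nx * nx + ny * ny <= 1.0
    if shape.type == "path":
        pts = g["points"]
        if g["closed"]:
            return _point_in_polygon(p.x, p.y, pts)
        half = dict(shape.style).get("width", LINK_WIDTH) / 2.0
        return any(_dist_point_segment(p.x, p.y, a[0], a[1], b[0], b[1])
                   <= half for a, b in zip(pts, pts[1:]))
    if shape.type == "text":
        return _shape_bounds(shape).contains(p)
    return False


def hit_test(scene: Scene, p: GridPoint) -> Optional[str]:
    """Element id under a click, or None.

    Candidates are groups whose coarse bounds contain the point and whose
    precise shape test passes; the topmost layer wins, ties within a layer
    go to the group with the smallest total bounds area.
    """
    for layer in sorted(scene.layers, reverse=True):
        hits = []
        for g in scene.layers[layer]:
            if not any(b.contains(p) for b in g.bounds):
                continue
            if any(shape_hit(s, p) for s in g.shapes):
                area = sum(b.width * b.height for b in g.bounds)
                hits.append((area, g.element_id))
        if hits:
            hits.sort()
            return hits[0][1]
    return None


# ---------------------------------------------------------------------------
# JSON serialization


def _shape_to_doc(s: PrimitiveShape) -> dict:
    g = s.geom()
    if s.type == "path":
        g["points"] = [[x, y] for x, y in g["points"]]
    return {"type": s.type, "geometry": g, "style": dict(s.style)}


def _shape_from_doc(d: dict) -> PrimitiveShape:
    g = dict(d["geometry"])
    if d["type"] == "path":
        g["points"] = tuple((int(x), int(y)) for x, y in g["points"])
    return PrimitiveShape(d["type"], tuple(sorted(g.items())),
                          tuple(sorted(d["style"].items())))


def serialize_json(scene: Scene) -> str:
    """Deterministic JSON serialization of a scene (stable key order;
    byte-identical across repeated calls)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "grid_step": scene.grid_step,
        "bounds": [scene.bounds.x0, scene.bounds.y0,
                   scene.bounds.x1, scene.bounds.y1],
        "layers": [
            {
                "name": layer.name.lower(),
                "ordinal": int(layer),
                "groups": [
                    {
                        "id": g.element_id,
                        "shapes": [_shape_to_doc(s) for s in g.shapes],
                        "selected_shapes": [_shape_to_doc(s)
                                            for s in g.selected_shapes],
                        "bounds": [[b.x0, b.y0, b.x1, b.y1]
                                   for b in g.bounds],
                    }
                    for g in scene.layers.get(layer, [])
                ],
            }
            for layer in sorted(DrawLayer)
        ],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def parse_json(text: str) -> Scene:
    doc = json.loads(text)
    errors = validate_scene_doc(doc)
    if errors:
        raise ValueError("invalid scene document: " + "; ".join(errors))
    layers: dict[DrawLayer, list[CacheGroup]] = {layer: [] for layer in DrawLayer}
    for ld in doc["layers"]:
        layer = DrawLayer(ld["ordinal"])
        for gd in ld["groups"]:
            layers[layer].append(CacheGroup(
                element_id=gd["id"], layer=layer,
                shapes=tuple(_shape_from_doc(s) for s in gd["shapes"]),
                selected_shapes=tuple(_shape_from_doc(s)
                                      for s in gd["selected_shapes"]),
                bounds=tuple(Rect(*map(int, b)) for b in gd["bounds"])))
    b = doc["bounds"]
    return Scene(layers=layers, bounds=Rect(*map(int, b)),
                 grid_step=int(doc["grid_step"]))


_SHAPE_GEOMETRY_KEYS = {
    "line": {"x1", "y1", "x2", "y2"},
    "rect": {"x", "y", "w", "h"},
    "ellipse": {"cx", "cy", "rx", "ry"},
    "path": {"points", "closed"},
    "text": {"x", "y", "text"},
}


def validate_scene_doc(doc) -> list[str]:
    """Check a parsed scene document against the export schema (see
    docs/schema.md).  Returns a list of human-readable problems."""
    errs: list[str] = []
    if not isinstance(doc, dict):
        return ["document is not an object"]
    for key in ("schema_version", "grid_step", "bounds", "layers"):
        if key not in doc:
            errs.append(f"missing top-level key {key!r}")
    if errs:
        return errs
    if doc["schema_version"] != SCHEMA_VERSION:
        errs.append(f"unsupported schema_version {doc['schema_version']!r}")
    if (not isinstance(doc["bounds"], list) or len(doc["bounds"]) != 4
            or not all(isinstance(v, int) for v in doc["bounds"])):
        errs.append("bounds must be [x0, y0, x1, y1] integers")
    if not isinstance(doc["layers"], list):
        return errs + ["layers must be a list"]
    seen_ordinals = []
    for li, ld in enumerate(doc["layers"]):
        where = f"layers[{li}]"
        if not isinstance(ld, dict) or not {"name", "ordinal",
                                            "groups"} <= set(ld):
            errs.append(f"{where}: needs name, ordinal, groups")
            continue
        seen_ordinals.append(ld["ordinal"])
        for gi, gd in enumerate(ld.get("groups", [])):
            gw = f"{where}.groups[{gi}]"
            if not isinstance(gd, dict) or not {"id", "shapes",
                                                "selected_shapes",
                                                "bounds"} <= set(gd):
                errs.append(f"{gw}: needs id, shapes, selected_shapes, bounds")
                continue
            for b in gd["bounds"]:
                if not (isinstance(b, list) and len(b) == 4):
                    errs.append(f"{gw}: malformed bounds entry {b!r}")
            for si, sd in enumerate(list(gd["shapes"])
                                    + list(gd["selected_shapes"])):
                sw = f"{gw}.shapes[{si}]"
                if not isinstance(sd, dict) or "type" not in sd:
                    errs.append(f"{sw}: missing type")
                    continue
                if sd["type"] not in _SHAPE_GEOMETRY_KEYS:
                    errs.append(f"{sw}: unknown type {sd['type']!r}")
                    continue
                need = _SHAPE_GEOMETRY_KEYS[sd["type"]]
                got = set(sd.get("geometry", {}))
                if got != need:
                    errs.append(f"{sw}: geometry keys {sorted(got)} != "
                                f"{sorted(need)}")
                if not isinstance(sd.get("style", {}), dict):
                    errs.append(f"{sw}: style must be an object")
    if seen_ordinals != sorted(seen_ordinals):
        errs.append("layers not in ascending ordinal order")
    return errs


# ---------------------------------------------------------------------------
# SVG output

_COLORS = {
    "gene": "#d8e6c9",
    "gene-baseline": "#3a5f22",
    "bubble": "#dfe8f2",
    "box": "#e8e3d4",
    "intercell": "#f2e0e0",
    "slash": "#555555",
    "outline": "#444444",
    "label": "#222222",
    "promote": "#2e7d32",
    "repress": "#b71c1c",
    "neutral": "#546e7a",
    "selection": "#ff9800",
    "module": "#c5cae9",
    "module-border": "#5c6bc0",
    "module-label": "#3949ab",
    "module-link": "#7986cb",
    "none": "none",
}


def _color(token) -> str:
    return _COLORS.get(str(token), str(token))


def _esc(text: str) -> str:
    return (str(text).replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def _shape_to_svg(s: PrimitiveShape) -> str:
    g = s.geom()
    st = dict(s.style)
    stroke = _color(st.get("stroke", "none"))
    fill = _color(st.get("fill", "none"))
    width = st.get("width", 1)
    opacity = st.get("opacity")
    op = f' opacity="{opacity}"' if opacity is not None else ""
    if s.type == "line":
        return (f'<line x1="{g["x1"]}" y1="{g["y1"]}" x2="{g["x2"]}" '
                f'y2="{g["y2"]}" stroke="{stroke}" stroke-width="{width}"'
                f'{op}/>')
    if s.type == "rect":
        return (f'<rect x="{g["x"]}" y="{g["y"]}" width="{g["w"]}" '
                f'height="{g["h"]}" fill="{fill}" stroke="{stroke}" '
                f'stroke-width="{width}"{op}/>')
    if s.type == "ellipse":
        return (f'<ellipse cx="{g["cx"]}" cy="{g["cy"]}" rx="{g["rx"]}" '
                f'ry="{g["ry"]}" fill="{fill}" stroke="{stroke}" '
                f'stroke-width="{width}"{op}/>')
    if s.type == "path":
        cmds = "M " + " L ".join(f"{x} {y}" for x, y in g["points"])
        if g["closed"]:
            cmds += " Z"
        return (f'<path d="{cmds}" fill="{fill}" stroke="{stroke}" '
                f'stroke-width="{width}"{op}/>')
    if s.type == "text":
        size = st.get("size", 12)
        return (f'<text x="{g["x"]}" y="{g["y"]}" font-size="{size}" '
                f'font-family="sans-serif" fill="{_color(st.get("fill", "label"))}"'
                f'{op}>{_esc(g["text"])}</text>')
    raise ValueError(f"unknown shape type {s.type!r}")


def write_svg(scene: Scene, selection: Optional[set[str]] = None) -> str:
    """Emit SVG 1.1: one element per primitive shape, in draw-layer order.

    Selection shapes are emitted (last, on top) only for element ids in
    ``selection``.
    """
    b = scene.bounds
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{b.x0} {b.y0} {max(b.width, 1)} {max(b.height, 1)}" '
        f'width="{max(b.width, 1)}" height="{max(b.height, 1)}">',
    ]
    for layer in sorted(scene.layers):
        lines.append(f'<g id="layer-{layer.name.lower()}">')
        for group in scene.layers[layer]:
            lines.append(f'<g id="{_esc(group.element_id)}">')
            for shape in group.shapes:
                lines.append(_shape_to_svg(shape))
            lines.append('</g>')
        lines.append('</g>')
    if selection:
        lines.append('<g id="layer-selection-active">')
        for layer in sorted(scene.layers):
            for group in scene.layers[layer]:
                if group.element_id in selection:
                    for shape in group.selected_shapes:
                        lines.append(_shape_to_svg(shape))
        lines.append('</g>')
    lines.append('</svg>')
    return "\n".join(lines) + "\n"
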