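"""Stacked automatic layout.

The stacked strategy places nodes in bounded rows and routes every link
tree through reserved geometry: horizontal runs live only in a track band
above each node row (one track per source that needs that row), and
vertical runs between rows live only in a shared spine band down the left
side of the block (one column per source).  The result spends far more
"link ink" than a crossing-minimizing router would, but it is completely
predictable: every route can be reconstructed by eye from the source's
track and spine assignments, and no two trees ever share a collinear run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core_model import GrnModel, Link, NodeKind, Sign, UnknownNodeError
from .grid_geometry import (GRID_STEP, GridPoint, LinkTree, Rect, Segment,
                            is_orthogonal, snap)


class TargetGrouping(enum.Enum):
    ORDER_TARGETS_BY_SOURCE = "order-targets-by-source"
    INPUT_ORDER = "input-order"


@dataclass(frozen=True)
class StackedParams:
    """Knobs of the stacked strategy (all lengths in grid units).

    max_row_size caps how many nodes share a row; track_pitch and
    spine_pitch are the spacing between reserved tracks / spine columns;
    row_gap separates a row's bottom from the next row's track band;
    node_gap separates footprints within a row.
    """

    max_row_size: int = 20
    target_grouping: TargetGrouping = TargetGrouping.ORDER_TARGETS_BY_SOURCE
    row_gap: int = 40
    track_pitch: int = GRID_STEP
    spine_pitch: int = GRID_STEP
    node_gap: int = 20

    def __post_init__(self) -> None:
        if self.max_row_size < 1:
            raise ValueError("max_row_size must be >= 1")
        for name in ("row_gap", "track_pitch", "spine_pitch", "node_gap"):
            v = getattr(self, name)
            if v <= 0 or v % GRID_STEP:
                raise ValueError(f"{name} must be a positive multiple of "
                                 f"the grid step ({GRID_STEP})")


@dataclass
class Layout:
    """Node placements plus link-tree geometry on the grid."""

    placements: dict[str, Rect]
    trees: dict[str, LinkTree]
    bounds: Rect
    #: strategy-specific geometry (row membership, band extents, ...) kept
    #: for audits and rendering; not part of layout equality
    meta: dict = field(default_factory=dict, compare=False)

    def all_segments(self) -> list[Segment]:
        out = []
        for src in sorted(self.trees):
            out.extend(self.trees[src].segments())
        return out


class EmptySubsetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Node ordering


def order_targets_by_source(model: GrnModel) -> list[str]:
    """Ordering used by the "Order Targets by Source" grouping.

    Sources (out-degree >= 1) come first in id order; pure targets follow,
    grouped by their input signature (the sorted set of sources feeding
    them), groups in signature order, ids sorted within a group.  Finally
    each non-gene node feeding exactly one gene is pulled adjacent to that
    gene, so the pair lands in the same row side by side.
    """
    sources = model.sources()
    src_set = set(sources)
    targets = [n for n in sorted(model.nodes) if n not in src_set]
    targets.sort(key=lambda n: (model.input_signature(n), n))
    return _group_non_genes(model, sources + targets)


def input_order(model: GrnModel) -> list[str]:
    """Plain deterministic ordering: node ids sorted."""
    return _group_non_genes(model, sorted(model.nodes))


def _group_non_genes(model: GrnModel, ordered: list[str]) -> list[str]:
    """Move each non-gene node that feeds exactly one gene to sit directly
    before that gene (genes stay first-class; satellites cluster on them)."""
    moved: dict[str, list[str]] = {}
    keep: list[str] = []
    for nid in ordered:
        node = model.nodes[nid]
        outs = model.outbound_links(nid)
        fed = {l.target for l in outs}
        if (node.kind is not NodeKind.GENE and len(fed) == 1):
            gene = next(iter(fed))
            if gene != nid and model.nodes[gene].kind is NodeKind.GENE:
                moved.setdefault(gene, []).append(nid)
                continue
        keep.append(nid)
    out: list[str] = []
    for nid in keep:
        out.extend(moved.pop(nid, []))
        out.append(nid)
    for gene in sorted(moved):  # fed gene absent from ordering (subset runs)
        out.extend(moved[gene])
    return out


def assign_rows(ordered: list[str], params: StackedParams,
                model: Optional[GrnModel] = None) -> list[list[str]]:
    """Chunk the ordering into rows of at most ``max_row_size`` nodes.

    Row-major fill; concatenating the rows reproduces the input order.  A
    row break that would strand a non-gene node away from the gene it
    (solely) feeds is moved one slot earlier so the pair shares the next
    row, capacity permitting.
    """
    if not ordered:
        raise ValueError("cannot assign rows of an empty ordering")
    rows: list[list[str]] = [[]]
    for i, nid in enumerate(ordered):
        if len(rows[-1]) >= params.max_row_size:
            rows.append([])
        rows[-1].append(nid)
        if (model is not None and len(rows[-1]) == params.max_row_size
                and i + 1 < len(ordered) and len(rows[-1]) > 1):
            # would the break separate a feeder non-gene from its gene?
            last, nxt = rows[-1][-1], ordered[i + 1]
            if (model.nodes[last].kind is not NodeKind.GENE
                    and model.nodes[nxt].kind is NodeKind.GENE
                    and {l.target for l in model.outbound_links(last)} == {nxt}):
                rows[-1].pop()
                rows.append([last])
    return rows


# ---------------------------------------------------------------------------
# Placement


#: Horizontal margin between the spine band and the node block.
_BLOCK_MARGIN = 2 * GRID_STEP


def _band_sources(model: GrnModel, rows: list[list[str]],
                  global_sources: list[str]) -> list[list[str]]:
    """Per row, the sources whose tree needs a horizontal track there:
    sources placed in the row (their launch ascends into it) plus sources
    targeting any node in the row.  Ordered by global source order."""
    row_of = {nid: i for i, row in enumerate(rows) for nid in row}
    need: list[set[str]] = [set() for _ in rows]
    for s in global_sources:
        if s in row_of:
            need[row_of[s]].add(s)
        for l in model.outbound_links(s):
            if l.target in row_of:
                need[row_of[l.target]].add(s)
    order = {s: i for i, s in enumerate(global_sources)}
    return [sorted(b, key=order.__getitem__) for b in need]


def _inbound_pad_keys(model: GrnModel, nid: str) -> list[tuple[str, Sign]]:
    """Distinct (source, sign) pairs feeding ``nid`` — one landing pad
    slot each — ordered by global source order then sign."""
    return sorted({(l.source, l.sign) for l in model.inbound_links(nid)},
                  key=lambda k: (k[0], int(k[1])))


def _placement_width(model: GrnModel, nid: str) -> int:
    """Footprint width, widened so every landing pad slot fits on the top
    edge (one grid slot per inbound (source, sign), plus the launch slot)."""
    fp = model.nodes[nid].footprint
    n_in = len(_inbound_pad_keys(model, nid))
    need = (n_in + 2) * GRID_STEP
    return max(fp.width, need)


def place_rows(rows: list[list[str]], params: StackedParams,
               model: GrnModel,
               pad_model: Optional[GrnModel] = None) -> tuple[dict[str, Rect], dict]:
    """Place rows top to bottom with reserved geometry.

    Above each row sits a track band of height (#sources needing the row) x
    track_pitch; left of the whole block sits a spine band of width
    (#sources) x spine_pitch.  No footprint enters a reserved band.
    Returns (placements, geometry metadata).  ``pad_model``, when given, is
    a super-model whose inbound links decide landing-pad slot counts (used
    by the overlay-driven layout so inter-module inputs get slots too).
    """
    pad_model = pad_model or model
    global_sources = model.sources()
    bands = _band_sources(model, rows, global_sources)
    spine_x0 = 0
    spine_x1 = spine_x0 + len(global_sources) * params.spine_pitch
    content_x0 = spine_x1 + _BLOCK_MARGIN

    placements: dict[str, Rect] = {}
    track_y: dict[tuple[int, str], int] = {}
    track_bands: list[tuple[int, int]] = []
    row_tops: list[int] = []
    y = 0
    for i, row in enumerate(rows):
        band_h = len(bands[i]) * params.track_pitch
        track_bands.append((y, y + band_h))
        for k, s in enumerate(bands[i]):
            track_y[(i, s)] = y + k * params.track_pitch
        row_top = y + band_h
        row_tops.append(row_top)
        x = content_x0
        row_h = 0
        for nid in row:
            fp = model.nodes[nid].footprint
            w = _placement_width(pad_model, nid)
            placements[nid] = Rect(x, row_top, x + w, row_top + fp.height)
            row_h = max(row_h, fp.height)
            x += w + params.node_gap
        y = row_top + row_h + params.row_gap

    meta = {
        "strategy": "stacked",
        "rows": [list(r) for r in rows],
        "row_of": {nid: i for i, row in enumerate(rows) for nid in row},
        "sources": list(global_sources),
        "band_sources": [list(b) for b in bands],
        "track_bands": track_bands,
        "track_y": track_y,
        "row_tops": row_tops,
        "spine_band": (spine_x0, spine_x1),
        "spine_x": {s: spine_x0 + j * params.spine_pitch
                    for j, s in enumerate(global_sources)},
        "content_x0": content_x0,
    }
    return placements, meta


# ---------------------------------------------------------------------------
# Routing


def launch_pad(placement: Rect) -> GridPoint:
    """Launch pad: top-center of the source footprint, snapped to the grid
    (always interior to the top edge for footprints >= 2 grid steps wide)."""
    x = snap((placement.x0 + placement.x1) / 2.0)
    if x >= placement.x1:
        x = placement.x1 - GRID_STEP
    if x < placement.x0:
        x = placement.x0
    return GridPoint(x, placement.y0)


def landing_pads(model: GrnModel, placements: dict[str, Rect],
                 target: str) -> dict[tuple[str, Sign], GridPoint]:
    """Landing pads on the target's top edge: one grid slot per inbound
    (source, sign) pair, assigned left to right in global source order,
    skipping the target's own launch slot so an ascent never shares x with
    a drop."""
    rect = placements[target]
    own_launch_x = launch_pad(rect).x if model.outbound_links(target) else None
    xs = [x for x in range(rect.x0, rect.x1, GRID_STEP) if x != own_launch_x]
    pads: dict[tuple[str, Sign], GridPoint] = {}
    for i, key in enumerate(_inbound_pad_keys(model, target)):
        if i >= len(xs):
            raise AssertionError(
                f"node {target!r} placement too narrow for {i + 1} pads")
        pads[key] = GridPoint(xs[i], rect.y0)
    return pads


def _build_run(tree: LinkTree, anchor_id: int, y: int,
               station_xs: Iterable[int]) -> dict[int, int]:
    """Build one horizontal run along track ``y``: a left chain and a right
    chain of corners hanging off the anchor, one corner per station x.
    Chains are created outward from the anchor so every edge covers a
    disjoint x interval.  Returns x -> corner id (anchor included)."""
    anchor_x = tree.points[anchor_id].x
    corners = {anchor_x: anchor_id}
    left = sorted((x for x in station_xs if x < anchor_x), reverse=True)
    right = sorted(x for x in station_xs if x > anchor_x)
    for chain in (left, right):
        parent = anchor_id
        for x in chain:
            parent = tree.add_corner(parent, GridPoint(x, y))
            corners[x] = parent
    return corners


def route_links_stacked(model: GrnModel, placements: dict[str, Rect],
                        meta: dict, params: StackedParams,
                        pad_model: Optional[GrnModel] = None) -> dict[str, LinkTree]:
    """Route one link tree per source through the reserved geometry.

    Within the source's own row band the tree runs horizontally from its
    launch ascent; targets in other rows are reached by running left to the
    source's spine column, travelling vertically, and re-entering the
    target row's band on the source's track there.  Every landing is a
    single vertical drop from the track onto the target's top edge.
    """
    pad_model = pad_model or model
    row_of: dict[str, int] = meta["row_of"]
    track_y: dict[tuple[int, str], int] = meta["track_y"]
    spine_x: dict[str, int] = meta["spine_x"]

    trees: dict[str, LinkTree] = {}
    for s in meta["sources"]:
        outs = model.outbound_links(s)
        if not outs:
            continue
        r_s = row_of[s]
        lp = launch_pad(placements[s])
        tree = LinkTree(s, lp)
        home_y = track_y[(r_s, s)]
        anchor = tree.add_corner(tree.root_id, GridPoint(lp.x, home_y))

        by_row: dict[int, list[tuple[GridPoint, Link]]] = {}
        for l in outs:
            pad = landing_pads(pad_model, placements, l.target)[(s, l.sign)]
            by_row.setdefault(row_of[l.target], []).append((pad, l))

        other_rows = sorted(r for r in by_row if r != r_s)
        sx = spine_x[s]

        # home-row run: same-row pads plus (if needed) the spine exit
        home_stations = [p.x for p, _ in by_row.get(r_s, [])]
        if other_rows:
            home_stations.append(sx)
        home_corners = _build_run(tree, anchor, home_y, home_stations)

        run_corners: dict[int, dict[int, int]] = {r_s: home_corners}
        if other_rows:
            spine_entry = home_corners[sx]
            up_parent = down_parent = spine_entry
            for r in sorted((r for r in other_rows if r < r_s), reverse=True):
                up_parent = tree.add_corner(up_parent,
                                            GridPoint(sx, track_y[(r, s)]))
                run_corners[r] = _build_run(
                    tree, up_parent, track_y[(r, s)],
                    [p.x for p, _ in by_row[r]])
            for r in (r for r in other_rows if r > r_s):
                down_parent = tree.add_corner(down_parent,
                                              GridPoint(sx, track_y[(r, s)]))
                run_corners[r] = _build_run(
                    tree, down_parent, track_y[(r, s)],
                    [p.x for p, _ in by_row[r]])

        for r in sorted(by_row):
            for pad, l in sorted(by_row[r], key=lambda pl: pl[0].x):
                tree.add_leaf(run_corners[r][pad.x], pad, l.target, l.sign)
        trees[s] = tree
    return trees


# ---------------------------------------------------------------------------
# Top-level strategy


def stacked_layout(model: GrnModel, params: Optional[StackedParams] = None,
                   node_subset: Optional[Iterable[str]] = None,
                   pad_model: Optional[GrnModel] = None) -> Layout:
    """Run the full stacked strategy: order, chunk into rows, place with
    reserved bands, route.  A pure function of (model, params, subset)."""
    params = params or StackedParams()
    if node_subset is not None:
        subset = set(node_subset)
        if not subset:
            raise EmptySubsetError("node subset must be non-empty")
        model = model.submodel(subset)
    if not model.nodes:
        return Layout({}, {}, Rect(0, 0, 0, 0), {"strategy": "stacked"})
    if params.target_grouping is TargetGrouping.ORDER_TARGETS_BY_SOURCE:
        ordered = order_targets_by_source(model)
    else:
        ordered = input_order(model)
    rows = assign_rows(ordered, params, model)
    placements, meta = place_rows(rows, params, model, pad_model)
    trees = route_links_stacked(model, placements, meta, params, pad_model)
    bounds = _layout_bounds(placements, trees)
    return Layout(placements=placements, trees=trees, bounds=bounds, meta=meta)


def _layout_bounds(placements: dict[str, Rect],
                   trees: dict[str, LinkTree]) -> Rect:
    rects = list(placements.values())
    for t in trees.values():
        for p in t.points.values():
            rects.append(Rect(p.x, p.y, p.x, p.y))
    if not rects:
        return Rect(0, 0, 0, 0)
    b = Rect.bounding(rects)
    return Rect(b.x0 - GRID_STEP, b.y0 - GRID_STEP,
                b.x1 + GRID_STEP, b.y1 + GRID_STEP)
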