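"""Network overlays and the overlay-driven automatic layout.

An overlay annotates a GRN with named *modules* (One-Box node groups) and
directed *module links* expressing how the modules interact.  The
overlay-driven layout turns that annotation into a drawing: each module's
members are laid out internally with the stacked strategy, module boxes
are repositioned and enlarged so they contain their stacked content while
preserving the relative horizontal and vertical ordering of the original
box centers, and the node-level links that cross module boundaries are
routed orthogonally through the channels between boxes, leaving and
entering each box on the side indicated by the drawn module link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .core_model import GrnModel, Sign
from .grid_geometry import (GRID_STEP, GridPoint, LinkTree, Rect, Segment,
                            is_orthogonal, snap)
from .link_tools import (NoSolutionError, ObstacleSet, _dijkstra_attach,
                         _ForeignIndex, _compress)
from .stacked_layout import (Layout, StackedParams, landing_pads, launch_pad,
                             stacked_layout)


class ModuleType:
    ONE_BOX = "one_box"


@dataclass(frozen=True)
class NetworkModule:
    name: str
    members: frozenset[str]
    box: Optional[Rect] = None
    type: str = ModuleType.ONE_BOX

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.name!r} has no members")


@dataclass(frozen=True)
class ModuleLink:
    source: str
    target: str
    sign: Sign = Sign.PROMOTE
    waypoints: tuple[GridPoint, ...] = ()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"module link {self.source!r} to itself")


@dataclass
class NetworkOverlay:
    name: str
    modules: list[NetworkModule]
    module_links: list[ModuleLink] = field(default_factory=list)
    intensity: float = 1.0

    def module_of(self) -> dict[str, str]:
        """node id -> module name; raises on double assignment."""
        out: dict[str, str] = {}
        for m in self.modules:
            for nid in m.members:
                if nid in out:
                    raise ValueError(
                        f"node {nid!r} in both {out[nid]!r} and {m.name!r}")
                out[nid] = m.name
        return out

    def by_name(self) -> dict[str, NetworkModule]:
        return {m.name: m for m in self.modules}


@dataclass(frozen=True)
class OverlayProblem:
    kind: str   # missing-module-link | crooked-link | unassigned-node | ...
    detail: str
    blocking: bool = True

    def __str__(self) -> str:
        tag = "error" if self.blocking else "warning"
        return f"[{tag}] {self.kind}: {self.detail}"


class OverlayValidationError(ValueError):
    def __init__(self, problems: list[OverlayProblem]):
        self.problems = problems
        super().__init__("overlay failed validation:\n"
                         + "\n".join(str(p) for p in problems))


def validate_overlay(model: GrnModel, overlay: NetworkOverlay
                     ) -> list[OverlayProblem]:
    """Audit an overlay against a model.

    Blocking problems: a node-level link crossing from module A to module B
    with no A->B module link drawn; a module link with a non-orthogonal
    ("crooked") waypoint segment; a member id unknown to the model; a node
    claimed by two modules.  Nodes assigned to no module are a warning
    only (they are laid out in a trailing pseudo-module).
    """
    problems: list[OverlayProblem] = []
    seen_names: set[str] = set()
    member_of: dict[str, str] = {}
    for m in overlay.modules:
        if m.name in seen_names:
            problems.append(OverlayProblem(
                "duplicate-module-name", m.name))
        seen_names.add(m.name)
        if m.type != ModuleType.ONE_BOX:
            problems.append(OverlayProblem(
                "unsupported-module-type",
                f"{m.name}: only One-Box modules support overlay-driven "
                f"layout"))
        for nid in sorted(m.members):
            if nid not in model.nodes:
                problems.append(OverlayProblem(
                    "unknown-member", f"{m.name}: {nid}"))
            elif nid in member_of:
                problems.append(OverlayProblem(
                    "duplicate-assignment",
                    f"{nid} in both {member_of[nid]} and {m.name}"))
            else:
                member_of[nid] = m.name

    drawn = {(l.source, l.target) for l in overlay.module_links}
    missing: set[tuple[str, str]] = set()
    for l in model.sorted_links():
        a, b = member_of.get(l.source), member_of.get(l.target)
        if a is None or b is None or a == b:
            continue
        if (a, b) not in drawn:
            missing.add((a, b))
    for a, b in sorted(missing):
        problems.append(OverlayProblem(
            "missing-module-link",
            f"node links cross {a} -> {b} but no module link is drawn"))

    for l in overlay.module_links:
        for p, q in zip(l.waypoints, l.waypoints[1:]):
            if p != q and not is_orthogonal(Segment(p, q)):
                problems.append(OverlayProblem(
                    "crooked-link",
                    f"{l.source} -> {l.target}: segment {p} -> {q} "
                    f"is not orthogonal"))

    for nid in sorted(set(model.nodes) - set(member_of)):
        problems.append(OverlayProblem("unassigned-node", nid,
                                       blocking=False))
    return problems


# ---------------------------------------------------------------------------
# Module box helpers


class UnplacedMemberError(KeyError):
    pass


#: padding between member footprints and the module box edge, grid units
BOX_PADDING = 2 * GRID_STEP
#: free channel kept between packed module boxes, grid units
CHANNEL_GAP = 6 * GRID_STEP


def resize_module_to_bounds(module: NetworkModule,
                            layout: Layout) -> NetworkModule:
    """Shrink-wrap the box: the minimal grid-aligned rectangle containing
    every member footprint, plus padding.  Idempotent."""
    rects = []
    for nid in sorted(module.members):
        if nid not in layout.placements:
            raise UnplacedMemberError(nid)
        rects.append(layout.placements[nid])
    box = Rect.bounding(rects).inflate(BOX_PADDING)
    return replace(module, box=box)


_SIDES = ("north", "east", "south", "west")


def _exit_entry_sides(link: ModuleLink, box_a: Rect, box_b: Rect
                      ) -> tuple[str, str]:
    """Which side the drawn module link leaves A by and enters B by,
    read off its first/last waypoint segments (dominant-axis fallback)."""

    def side_from_dir(dx: int, dy: int, leaving: bool) -> str:
        if dx == dy == 0:
            return ""
        if abs(dx) >= abs(dy):
            if leaving:
                return "east" if dx > 0 else "west"
            return "west" if dx > 0 else "east"
        if leaving:
            return "south" if dy > 0 else "north"
        return "north" if dy > 0 else "south"

    exit_side = entry_side = ""
    wps = link.waypoints
    if len(wps) >= 2:
        exit_side = side_from_dir(wps[1].x - wps[0].x, wps[1].y - wps[0].y,
                                  leaving=True)
        entry_side = side_from_dir(wps[-1].x - wps[-2].x,
                                   wps[-1].y - wps[-2].y, leaving=False)
    if not exit_side or not entry_side:
        cax, cay = box_a.center
        cbx, cby = box_b.center
        fallback_exit = side_from_dir(int(cbx - cax), int(cby - cay), True)
        fallback_entry = side_from_dir(int(cbx - cax), int(cby - cay), False)
        exit_side = exit_side or fallback_exit
        entry_side = entry_side or fallback_entry
    return exit_side, entry_side


def _portal(box: Rect, side: str, lane: int) -> GridPoint:
    """A grid point just outside ``box`` on ``side``; ``lane`` spreads the
    portals of different sources so their runs never share a line."""
    cx = snap((box.x0 + box.x1) / 2)
    cy = snap((box.y0 + box.y1) / 2)
    d = GRID_STEP + lane
    if side == "east":
        return GridPoint(box.x1 + d, cy)
    if side == "west":
        return GridPoint(box.x0 - d, cy)
    if side == "south":
        return GridPoint(cx, box.y1 + d)
    return GridPoint(cx, box.y0 - d)


# ---------------------------------------------------------------------------
# The overlay-driven layout


def overlay_driven_layout(model: GrnModel, overlay: NetworkOverlay,
                          params: Optional[StackedParams] = None
                          ) -> tuple[Layout, NetworkOverlay]:
    """Lay out a network per its overlay.

    Raises OverlayValidationError (echoing every problem) when validation
    finds blockers.  Returns the merged Layout and a new overlay whose
    boxes wrap the stacked content and whose module links are re-drawn
    between the new boxes.
    """
    params = params or StackedParams()
    problems = validate_overlay(model, overlay)
    blockers = [p for p in problems if p.blocking]
    if blockers:
        raise OverlayValidationError(blockers)

    member_of = overlay.module_of()
    modules = list(overlay.modules)
    unassigned = sorted(set(model.nodes) - set(member_of))
    if unassigned:
        below = max((m.box.y1 for m in modules if m.box), default=0)
        right = max((m.box.x1 for m in modules if m.box), default=0)
        pseudo = NetworkModule(name="unassigned",
                               members=frozenset(unassigned),
                               box=Rect(right + CHANNEL_GAP, below + CHANNEL_GAP,
                                        right + 2 * CHANNEL_GAP,
                                        below + 2 * CHANNEL_GAP))
        modules.append(pseudo)
        for nid in unassigned:
            member_of[nid] = "unassigned"

    # per-module stacked sub-layouts (pads sized for the full model)
    sublayouts: dict[str, Layout] = {}
    for m in modules:
        sublayouts[m.name] = stacked_layout(model, params,
                                            node_subset=m.members,
                                            pad_model=model)

    new_boxes = _pack_boxes(modules, sublayouts)

    # translate each sub-layout into its packed box
    placements: dict[str, Rect] = {}
    trees: dict[str, LinkTree] = {}
    module_meta: dict[str, dict] = {}
    for m in modules:
        sub = sublayouts[m.name]
        box = new_boxes[m.name]
        dx = box.x0 + BOX_PADDING - sub.bounds.x0
        dy = box.y0 + BOX_PADDING - sub.bounds.y0
        moved = _translate_layout(sub, dx, dy)
        placements.update(moved.placements)
        trees.update(moved.trees)
        module_meta[m.name] = {"box": box, "members": sorted(m.members),
                               "sublayout": moved}

    new_overlay_modules = [replace(m, box=new_boxes[m.name]) for m in modules
                           if m.name != "unassigned"]

    # route inter-module node links
    drawn_links = {(l.source, l.target): l for l in overlay.module_links}
    routed_waypoints = _route_inter_module(
        model, overlay, member_of, new_boxes, placements, trees, drawn_links)

    from .stacked_layout import _layout_bounds
    layout = Layout(placements=placements, trees=trees,
                    bounds=_layout_bounds(placements, trees),
                    meta={"strategy": "overlay", "modules": module_meta})

    new_links = []
    for (a, b) in sorted({(l.source, l.target) for l in overlay.module_links}):
        wps = routed_waypoints.get(
            (a, b), _box_center_elbow(new_boxes[a], new_boxes[b]))
        new_links.append(ModuleLink(source=a, target=b, waypoints=wps))
    result_overlay = NetworkOverlay(name=overlay.name,
                                    modules=new_overlay_modules,
                                    module_links=new_links,
                                    intensity=overlay.intensity)
    return layout, result_overlay


def _translate_layout(sub: Layout, dx: int, dy: int) -> Layout:
    placements = {n: r.translate(dx, dy) for n, r in sub.placements.items()}
    trees = {}
    for s, t in sub.trees.items():
        nt = t.copy()
        nt.points = {nid: GridPoint(p.x + dx, p.y + dy)
                     for nid, p in t.points.items()}
        trees[s] = nt
    return Layout(placements=placements, trees=trees,
                  bounds=sub.bounds.translate(dx, dy), meta=dict(sub.meta))


def _pack_boxes(modules: list[NetworkModule],
                sublayouts: dict[str, Layout]) -> dict[str, Rect]:
    """Order-preserving coordinate compaction.

    Boxes are sized to their stacked content plus padding, then assigned
    disjoint x extents in the order of the original box-center x
    coordinates, and y extents likewise — so the strict orderings of
    original centers are preserved in both axes, and boxes are pairwise
    disjoint with a channel gap without solving a packing problem.
    """
    sizes: dict[str, tuple[int, int]] = {}
    for m in modules:
        b = sublayouts[m.name].bounds
        sizes[m.name] = (b.width + 2 * BOX_PADDING,
                         b.height + 2 * BOX_PADDING)

    def center(m: NetworkModule) -> tuple[float, float]:
        return m.box.center if m.box is not None else (0.0, 0.0)

    x_order = sorted(modules, key=lambda m: (center(m)[0], m.name))
    y_order = sorted(modules, key=lambda m: (center(m)[1], m.name))
    xs: dict[str, int] = {}
    cursor = 0
    for m in x_order:
        xs[m.name] = cursor
        cursor += sizes[m.name][0] + CHANNEL_GAP
    ys: dict[str, int] = {}
    cursor = 0
    for m in y_order:
        ys[m.name] = cursor
        cursor += sizes[m.name][1] + CHANNEL_GAP
    return {m.name: Rect(xs[m.name], ys[m.name],
                         xs[m.name] + sizes[m.name][0],
                         ys[m.name] + sizes[m.name][1])
            for m in modules}


def _box_center_elbow(a: Rect, b: Rect) -> tuple[GridPoint, ...]:
    ax, ay = (snap(v) for v in a.center)
    bx, by = (snap(v) for v in b.center)
    pts = [GridPoint(ax, ay)]
    if bx != ax:
        pts.append(GridPoint(bx, ay))
    if by != ay:
        pts.append(GridPoint(bx, by))
    if len(pts) == 1:
        pts.append(GridPoint(bx + GRID_STEP, by))
    return tuple(pts)


def _route_inter_module(model: GrnModel, overlay: NetworkOverlay,
                        member_of: dict[str, str], boxes: dict[str, Rect],
                        placements: dict[str, Rect],
                        trees: dict[str, LinkTree],
                        drawn_links: dict) -> dict[tuple[str, str],
                                                   tuple[GridPoint, ...]]:
    """Route every node link that crosses module boundaries.

    Per link the route has three legs: source tree -> exit portal (inside
    the source box), exit portal -> entry portal (between boxes, on a
    per-source lane so different sources never share a line), and entry
    portal -> landing pad (inside the target box).  Legs attach to the
    source's growing tree wherever they first meet it, merging shared
    trunks.  Returns representative waypoints per module pair for the
    re-drawn module links.
    """
    inter = [l for l in model.sorted_links()
             if member_of[l.source] != member_of[l.target]]
    if not inter:
        return {}
    sources = sorted({l.source for l in inter})
    # lanes spread portal offsets across the channel gap; collisions beyond
    # five sources are resolved by the router's foreign-segment avoidance
    lane_of = {s: (i % 5) * GRID_STEP for i, s in enumerate(sources)}
    node_rects = [placements[n] for n in sorted(placements)]
    all_boxes = [boxes[n] for n in sorted(boxes)]
    rep_waypoints: dict[tuple[str, str], tuple[GridPoint, ...]] = {}

    for s in sources:
        if s not in trees:
            trees[s] = LinkTree(s, launch_pad(placements[s]))
        tree = trees[s]
        # full-resolution point map of the current tree for attach-routing
        parent_pt = _expand_tree(tree)
        foreign_segs = []
        for other, t in sorted(trees.items()):
            if other != s:
                foreign_segs.extend(t.segments())
        foreign = _ForeignIndex(foreign_segs)
        box_a = boxes[member_of[s]]
        blocked: list[str] = []
        for l in [l for l in inter if l.source == s]:
            mod_b = member_of[l.target]
            box_b = boxes[mod_b]
            drawn = drawn_links.get((member_of[s], mod_b))
            exit_side, entry_side = _exit_entry_sides(
                drawn if drawn is not None
                else ModuleLink(member_of[s], mod_b), box_a, box_b)
            e_portal = _portal(box_a, exit_side, lane_of[s])
            p_portal = _portal(box_b, entry_side, lane_of[s])
            pad = landing_pads(model, placements, l.target)[(s, l.sign)]

            ok = True
            for goal, region, hard_boxes in (
                (e_portal, box_a.inflate(4 * GRID_STEP + lane_of[s]), []),
                (p_portal, Rect.bounding([box_a, box_b]).inflate(
                    4 * GRID_STEP + lane_of[s]), all_boxes),
                (pad, box_b.inflate(4 * GRID_STEP + lane_of[s]), []),
            ):
                obstacles = ObstacleSet(
                    node_rects=node_rects + hard_boxes,
                    foreign_segments=[])
                path = _dijkstra_attach(parent_pt, goal, region, obstacles,
                                        foreign)
                if path is None:
                    ok = False
                    break
                for prev, cur in zip(path, path[1:]):
                    if cur not in parent_pt:
                        parent_pt[cur] = prev
            if not ok:
                blocked.append(l.target)
                continue
            key = (member_of[s], mod_b)
            rep_waypoints.setdefault(key, (e_portal, p_portal))
        if blocked:
            raise NoSolutionError(
                f"cannot route links of {s!r} to: " + ", ".join(blocked),
                blocked_targets=blocked)
        # rebuild the tree from the expanded map, keeping all leaves
        pads = {key: tree.points[nid] for key, nid in tree.leaf_ids.items()}
        for l in [l for l in inter if l.source == s]:
            pads[(l.target, l.sign)] = landing_pads(
                model, placements, l.target)[(s, l.sign)]
        trees[s] = _compress(s, tree.root, parent_pt, pads)
    return rep_waypoints


def _expand_tree(tree: LinkTree) -> dict[GridPoint, Optional[GridPoint]]:
    """Full-resolution (grid-step) point->parent map of a tree's geometry."""
    out: dict[GridPoint, Optional[GridPoint]] = {tree.root: None}
    for pid, cid in tree.edges():
        a, b = tree.points[pid], tree.points[cid]
        if a == b:
            continue
        seg = Segment(a, b)
        dx, dy = seg.direction
        steps = seg.length_l1() // GRID_STEP
        prev = a
        for i in range(1, steps + 1):
            cur = GridPoint(a.x + dx * i * GRID_STEP,
                            a.y + dy * i * GRID_STEP)
            if cur not in out:
                out[cur] = prev
            prev = cur
    return out
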