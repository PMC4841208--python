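"""Drawing-support tools: orthogonalize a roughed-in link tree, and repair
a malformed (self-crossing / overlapping) one.

The orthogonality tool is a local fixer: it never re-routes, it only
shifts and splits existing segments until every segment is axis-aligned.
Candidate fixes that cross node footprints, collinearly ride a foreign
tree's segments, or introduce a 180-degree reversal are rejected; when no
candidate survives the tool gives up on that segment and asks the caller
to supply guiding corners, exactly as a human would have to.

The overlap-repair tool is a re-router: it keeps the launch pad, the
landing pads and the set of targets, throws the malformed interior
geometry away, and re-routes each root-to-leaf path over a grid graph,
attaching each new path to the already-routed part of the tree so shared
prefixes merge back into trunk segments.
"""

from __future__ import annotations

import enum
import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .grid_geometry import (GRID_STEP, GridPoint, LinkTree, OverlapKind, Rect,
                            Segment, antiparallel, is_orthogonal,
                            segments_overlap, tree_targets)
from .stacked_layout import Layout


class OrthogonalizeMode(enum.Enum):
    MINIMIZE_SHIFTS = "minimize-shifts"


@dataclass
class ObstacleSet:
    """What a tree's geometry must stay clear of: node footprints (interiors
    are forbidden, boundaries may be touched) and other trees' segments
    (perpendicular crossings are fine, collinear riding is not)."""

    node_rects: list[Rect] = field(default_factory=list)
    foreign_segments: list[Segment] = field(default_factory=list)

    def segment_blocked(self, seg: Segment) -> bool:
        return (self._crosses_rect_interior(seg)
                or self._rides_foreign(seg))

    def _crosses_rect_interior(self, seg: Segment) -> bool:
        horizontal = seg.a.y == seg.b.y
        if horizontal:
            y = seg.a.y
            lo, hi = sorted((seg.a.x, seg.b.x))
            for r in self.node_rects:
                if r.y0 < y < r.y1 and max(lo, r.x0) < min(hi, r.x1):
                    return True
        else:
            x = seg.a.x
            lo, hi = sorted((seg.a.y, seg.b.y))
            for r in self.node_rects:
                if r.x0 < x < r.x1 and max(lo, r.y0) < min(hi, r.y1):
                    return True
        return False

    def _rides_foreign(self, seg: Segment) -> bool:
        for f in self.foreign_segments:
            if segments_overlap(seg, f).kind is OverlapKind.COLLINEAR_INTERVAL:
                return True
        return False

    def point_blocked(self, p: GridPoint) -> bool:
        return any(r.contains_strict(p) for r in self.node_rects)


class NoSolutionError(RuntimeError):
    """A geometry tool could not find a legal fix."""

    def __init__(self, message: str, *, segment: Optional[Segment] = None,
                 blocked_targets: Optional[list[str]] = None):
        super().__init__(message)
        self.segment = segment
        self.blocked_targets = blocked_targets or []


class AggregateGeometryError(RuntimeError):
    """Per-tree failures collected by the layout-wide tools; processing
    continued past each failure and the partial result is attached."""

    def __init__(self, errors: dict[str, Exception], layout: Layout):
        msgs = "; ".join(f"{s}: {e}" for s, e in sorted(errors.items()))
        super().__init__(f"{len(errors)} tree(s) failed: {msgs}")
        self.errors = errors
        self.layout = layout


# ---------------------------------------------------------------------------
# Orthogonalization


def _parent_away_dir(tree: LinkTree, nid: int):
    """Direction from ``nid`` toward its parent, or None."""
    pid = tree.parent.get(nid)
    if pid is None:
        return None
    a, b = tree.points[nid], tree.points[pid]
    return None if a == b else Segment(a, b).direction


def _child_away_dirs(tree: LinkTree, nid: int, at: GridPoint) -> set:
    """Directions from ``at`` toward ``nid``'s children."""
    out = set()
    for g in tree.children(nid):
        gp = tree.points[g]
        if gp != at:
            out.add(Segment(at, gp).direction)
    return out


def _bfs_edge_order(tree: LinkTree) -> list[tuple[int, int]]:
    order = []
    queue = [tree.root_id]
    while queue:
        nid = queue.pop(0)
        for c in tree.children(nid):
            order.append((nid, c))
            queue.append(c)
    return order


def orthogonalize_tree(tree: LinkTree, obstacles: Optional[ObstacleSet] = None,
                       mode: OrthogonalizeMode = OrthogonalizeMode.MINIMIZE_SHIFTS,
                       ) -> LinkTree:
    """Make every segment of ``tree`` axis-aligned with minimal disturbance.

    Pads (root and leaves) never move.  For each diagonal segment the
    candidates are, in cost order: the two elbow splits (cost 0; tie broken
    horizontal-first) and, for a movable interior child corner, snapping
    the corner onto the nearer axis (cost = L1 displacement).  Candidates
    whose segments hit obstacles or double back 180 degrees on an adjacent
    segment are discarded; if none survive a NoSolutionError identifies the
    offending segment.  Idempotent on already-orthogonal trees.
    """
    if mode is not OrthogonalizeMode.MINIMIZE_SHIFTS:
        raise ValueError(f"unsupported mode {mode}")
    obstacles = obstacles or ObstacleSet()
    out = tree.copy()
    pad_ids = set(out.leaf_ids.values()) | {out.root_id}

    for _pass in range(5):
        bad = [(p, c) for p, c in _bfs_edge_order(out)
               if out.points[p] != out.points[c]
               and not is_orthogonal(Segment(out.points[p], out.points[c]))]
        if not bad:
            return out
        for p, c in bad:
            a, b = out.points[p], out.points[c]
            if a == b or is_orthogonal(Segment(a, b)):
                continue  # fixed as a side effect of an earlier shift
            _fix_edge(out, p, c, obstacles, pad_ids)
    # verify
    for p, c in _bfs_edge_order(out):
        a, b = out.points[p], out.points[c]
        if a != b and not is_orthogonal(Segment(a, b)):
            raise NoSolutionError(
                f"segment {a}->{b} still diagonal after shift passes",
                segment=Segment(a, b))
    return out


def _fix_edge(tree: LinkTree, p: int, c: int, obstacles: ObstacleSet,
              pad_ids: set[int]) -> None:
    a, b = tree.points[p], tree.points[c]
    elbow_h = GridPoint(b.x, a.y)   # horizontal leg first
    elbow_v = GridPoint(a.x, b.y)   # vertical leg first
    candidates: list[tuple[int, int, str, object]] = [
        (0, 0, "elbow", elbow_h),
        (0, 1, "elbow", elbow_v),
    ]
    if c not in pad_ids:
        shift_h = GridPoint(b.x, a.y)  # child snapped to parent's y
        shift_v = GridPoint(a.x, b.y)  # child snapped to parent's x
        candidates.append((abs(b.y - a.y), 0, "shift", shift_h))
        candidates.append((abs(b.x - a.x), 1, "shift", shift_v))
    candidates.sort(key=lambda t: (t[0], t[1]))

    # 180-degree turns are a property of root-to-leaf paths: the new
    # geometry must not fold back along p's parent edge or along c's child
    # edges (a fold-back means equal away-directions at the shared corner).
    # Sibling branches sharing a direction are merely non-optimal geometry.
    p_parent_dir = _parent_away_dir(tree, p)

    for _cost, _tie, kind, pt in candidates:
        if kind == "elbow":
            segs = [Segment(a, pt), Segment(pt, b)]
            if Segment(a, pt).direction == p_parent_dir:
                continue
            if Segment(b, pt).direction in _child_away_dirs(tree, c, b):
                continue
            if any(obstacles.segment_blocked(s) for s in segs):
                continue
            mid = tree.add_corner(p, pt)
            tree.parent[c] = mid
            return
        else:  # shift the child corner onto an axis
            if pt == a:
                continue
            new_edge = Segment(a, pt)
            if new_edge.direction == p_parent_dir:
                continue
            child_dirs = _child_away_dirs(tree, c, pt)
            if any(tree.points[g] == pt for g in tree.children(c)):
                continue  # would create a degenerate child edge
            if Segment(pt, a).direction in child_dirs:
                continue
            if obstacles.segment_blocked(new_edge):
                continue
            if any(is_orthogonal(Segment(pt, tree.points[g]))
                   and obstacles.segment_blocked(Segment(pt, tree.points[g]))
                   for g in tree.children(c)):
                continue
            tree.points[c] = pt
            return
    if _fix_edge_multisplit(tree, p, c, obstacles, p_parent_dir):
        return
    raise NoSolutionError(
        f"cannot orthogonalize segment {a}->{b}: both elbow candidates "
        "blocked; add link corners for guidance",
        segment=Segment(a, b))


def _fix_edge_multisplit(tree: LinkTree, p: int, c: int,
                         obstacles: ObstacleSet, p_parent_dir) -> bool:
    """Last-resort split: replace the diagonal edge by an orthogonal
    polyline routed around the obstacles (still keeping both endpoints
    fixed and refusing 180-degree fold-backs at either end)."""
    a, b = tree.points[p], tree.points[c]
    if a.x % GRID_STEP or a.y % GRID_STEP or b.x % GRID_STEP or b.y % GRID_STEP:
        return False
    foreign = _ForeignIndex(obstacles.foreign_segments)
    base = Rect(min(a.x, b.x), min(a.y, b.y), max(a.x, b.x), max(a.y, b.y))
    forbid_first = frozenset([p_parent_dir]) if p_parent_dir else frozenset()
    forbid_goal_away = frozenset(d for d in _child_away_dirs(tree, c, b)
                                 if 0 in d)  # only orthogonal dirs can fold
    path = None
    for margin in (6 * GRID_STEP, 20 * GRID_STEP):
        path = _dijkstra_attach({a: None}, b, base.inflate(margin),
                                obstacles, foreign,
                                forbid_first=forbid_first,
                                forbid_goal_away=forbid_goal_away)
        if path is not None:
            break
    if path is None or len(path) < 2:
        return False
    # compress the full-resolution path into corner points
    corners = [pt for prev, pt, nxt in zip(path, path[1:], path[2:])
               if Segment(prev, pt).direction != Segment(pt, nxt).direction]
    cur = p
    for pt in corners:
        cur = tree.add_corner(cur, pt)
    tree.parent[c] = cur
    return True


# ---------------------------------------------------------------------------
# Overlap repair (grid-graph re-router)

_DIRS = (GridPoint(GRID_STEP, 0), GridPoint(0, GRID_STEP),
         GridPoint(-GRID_STEP, 0), GridPoint(0, -GRID_STEP))


def _sgn(v: int) -> int:
    return (v > 0) - (v < 0)


class _ForeignIndex:
    """Orientation-indexed foreign segments for O(1)-ish edge checks."""

    def __init__(self, segments: Iterable[Segment]):
        self.h: dict[int, list[tuple[int, int]]] = {}
        self.v: dict[int, list[tuple[int, int]]] = {}
        for s in segments:
            if s.a.y == s.b.y:
                lo, hi = sorted((s.a.x, s.b.x))
                self.h.setdefault(s.a.y, []).append((lo, hi))
            elif s.a.x == s.b.x:
                lo, hi = sorted((s.a.y, s.b.y))
                self.v.setdefault(s.a.x, []).append((lo, hi))
            # diagonal foreign segments cannot be ridden collinearly by an
            # orthogonal route; ignored here

    def edge_blocked(self, p: GridPoint, q: GridPoint) -> bool:
        if p.y == q.y:
            lo, hi = sorted((p.x, q.x))
            for a, b in self.h.get(p.y, ()):
                if max(lo, a) < min(hi, b):
                    return True
        else:
            lo, hi = sorted((p.y, q.y))
            for a, b in self.v.get(p.x, ()):
                if max(lo, a) < min(hi, b):
                    return True
        return False


def _dijkstra_attach(tree_pts: dict[GridPoint, GridPoint | None],
                     goal: GridPoint, region: Rect,
                     obstacles: ObstacleSet,
                     foreign: _ForeignIndex,
                     forbid_first: frozenset = frozenset(),
                     forbid_goal_away: frozenset = frozenset(),
                     ) -> Optional[list[GridPoint]]:
    """Shortest orthogonal path from the current tree to ``goal`` over the
    grid graph (A* on L1 distance, with a small turn penalty to prefer
    straight runs).  ``forbid_first`` bars leaving a source point in the
    given directions; ``forbid_goal_away`` bars arrivals whose away-
    direction from the goal is listed (both are fold-back guards).
    Returns the path from an existing tree point to the goal, or None."""
    if goal in tree_pts:
        return [goal]

    def h(p: GridPoint) -> int:
        return abs(p.x - goal.x) + abs(p.y - goal.y)

    # state: (point, incoming direction index or -1); priority = g + h
    best: dict[tuple[GridPoint, int], int] = {}
    heap: list[tuple[int, int, int, int, int]] = []
    for p in sorted(tree_pts):
        if region.x0 <= p.x <= region.x1 and region.y0 <= p.y <= region.y1:
            best[(p, -1)] = 0
            heapq.heappush(heap, (h(p), 0, p.x, p.y, -1))
    came: dict[tuple[GridPoint, int], tuple[GridPoint, int]] = {}
    goal_state = None
    while heap:
        _f, cost, x, y, d = heapq.heappop(heap)
        p = GridPoint(x, y)
        if best.get((p, d), None) != cost:
            continue
        if p == goal:
            goal_state = (p, d)
            break
        for nd, dv in enumerate(_DIRS):
            step_dir = (_sgn(dv.x), _sgn(dv.y))
            if d == -1 and step_dir in forbid_first:
                continue
            q = GridPoint(p.x + dv.x, p.y + dv.y)
            if not (region.x0 <= q.x <= region.x1
                    and region.y0 <= q.y <= region.y1):
                continue
            if q in tree_pts:
                continue  # never re-enter the tree: avoids self-crossings
            if q == goal and (-step_dir[0], -step_dir[1]) in forbid_goal_away:
                continue
            if q != goal and obstacles.point_blocked(q):
                continue
            if foreign.edge_blocked(p, q):
                continue
            step = GRID_STEP + (0 if d in (-1, nd) else 5)  # turn penalty
            nc = cost + step
            key = (q, nd)
            if nc < best.get(key, 1 << 60):
                best[key] = nc
                came[key] = (p, d)
                heapq.heappush(heap, (nc + h(q), nc, q.x, q.y, nd))
    if goal_state is None:
        return None
    path = [goal_state[0]]
    cur = goal_state
    while cur in came:
        cur = came[cur]
        path.append(cur[0])
    path.reverse()
    return path


def repair_tree(tree: LinkTree, obstacles: Optional[ObstacleSet] = None) -> LinkTree:
    """Re-route a (possibly severely malformed) tree into well-formed,
    orthogonal geometry with the same root, pads and targets.

    Each root-to-leaf connection is re-routed in sorted target order over a
    grid graph whose forbidden moves are node-footprint interiors, rides
    along foreign segments, and re-entry into the already-routed part of
    the tree; new paths attach to the routed tree wherever they first meet
    it, which merges shared prefixes into trunk segments.  Raises
    NoSolutionError naming the blocked targets if a connection cannot be
    routed; idempotent on already-clean trees.
    """
    obstacles = obstacles or ObstacleSet()
    root = tree.root
    pads = {key: tree.points[nid] for key, nid in tree.leaf_ids.items()}
    pad_order = sorted(pads, key=lambda k: (k[0], int(k[1])))
    foreign = _ForeignIndex(obstacles.foreign_segments)

    key_pts = [root] + [pads[k] for k in pad_order]
    base = Rect.bounding([Rect(p.x, p.y, p.x, p.y) for p in key_pts])
    blocked_targets: list[str] = []
    parent_pt: dict[GridPoint, GridPoint | None] = {root: None}
    for margin in (10 * GRID_STEP, 40 * GRID_STEP):
        region = base.inflate(margin)
        parent_pt = {root: None}
        blocked_targets = []
        for key in pad_order:
            path = _dijkstra_attach(parent_pt, pads[key], region, obstacles,
                                    foreign)
            if path is None:
                blocked_targets.append(key[0])
                continue
            for prev, cur in zip(path, path[1:]):
                parent_pt[cur] = prev
        if not blocked_targets:
            break
    if blocked_targets:
        raise NoSolutionError(
            "no obstacle-free channel to target(s): "
            + ", ".join(blocked_targets), blocked_targets=blocked_targets)
    return _compress(tree.source, root, parent_pt, pads)


def _compress(source: str, root: GridPoint,
              parent_pt: dict[GridPoint, GridPoint | None],
              pads: dict[tuple[str, object], GridPoint]) -> LinkTree:
    """Turn a full-resolution parent map into a LinkTree whose nodes are
    corners, branch points, the root, and the pads."""
    children: dict[GridPoint, list[GridPoint]] = {}
    for q, p in parent_pt.items():
        if p is not None:
            children.setdefault(p, []).append(q)
    keep = {root} | set(pads.values())

    def direction(a: GridPoint, b: GridPoint) -> tuple[int, int]:
        return Segment(a, b).direction

    out = LinkTree(source, root)
    pad_node: dict[GridPoint, int] = {root: out.root_id}
    # walk depth-first; collapse straight degree-2 runs
    stack = [(root, out.root_id)]
    while stack:
        pt, nid = stack.pop()
        for nxt in sorted(children.get(pt, ())):
            # extend along a straight run while the interior point is a
            # plain degree-2 corner we do not need to keep
            prev, cur = pt, nxt
            while (cur not in keep and len(children.get(cur, ())) == 1
                   and direction(prev, cur) == direction(
                       cur, children[cur][0])):
                prev, cur = cur, children[cur][0]
            cid = out.add_corner(nid, cur)
            pad_node[cur] = cid
            stack.append((cur, cid))
    for key in sorted(pads, key=lambda k: (k[0], int(k[1]))):
        out.leaf_ids[key] = pad_node[pads[key]]
    return out


# ---------------------------------------------------------------------------
# Layout-wide application


def _tree_obstacles(layout: Layout, source: str,
                    trees: dict[str, LinkTree]) -> ObstacleSet:
    segs: list[Segment] = []
    for s, t in sorted(trees.items()):
        if s != source:
            segs.extend(t.segments())
    return ObstacleSet(node_rects=[layout.placements[n]
                                   for n in sorted(layout.placements)],
                       foreign_segments=segs)


def _apply_all(layout: Layout, fn) -> Layout:
    trees = {s: t.copy() for s, t in layout.trees.items()}
    errors: dict[str, Exception] = {}
    for s in sorted(trees):
        try:
            trees[s] = fn(trees[s], _tree_obstacles(layout, s, trees))
        except NoSolutionError as e:
            errors[s] = e
    from .stacked_layout import _layout_bounds
    result = Layout(placements=dict(layout.placements), trees=trees,
                    bounds=_layout_bounds(layout.placements, trees),
                    meta=dict(layout.meta))
    if errors:
        raise AggregateGeometryError(errors, result)
    return result


def orthogonalize_all(layout: Layout,
                      mode: OrthogonalizeMode = OrthogonalizeMode.MINIMIZE_SHIFTS,
                      ) -> Layout:
    """Orthogonalize every tree, each against the node footprints and all
    other trees' current segments, in sorted source order."""
    return _apply_all(layout, lambda t, o: orthogonalize_tree(t, o, mode))


def repair_all(layout: Layout) -> Layout:
    """Repair every tree, each against the node footprints and all other
    trees' current segments, in sorted source order."""
    return _apply_all(layout, repair_tree)
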