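"""Integer-grid geometry: points, orthogonal segments, link trees.

All drawing geometry lives on an integer grid (screen convention: x grows
rightward, y grows downward, origin at the top left).  A *link tree* is the
hyperedge structure that carries every outbound link of one source node:
a rooted tree of corner points whose edges are the drawn segments, with one
leaf pad per (target, sign) pair.  Sharing trunk segments is what makes the
representation parsimonious compared to drawing one independent edge per
link — but it also means malformed geometry (collinearly overlapping or
self-crossing segments) makes mouse interaction ambiguous, hence the
well-formedness predicate here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

#: Grid step in drawing units.  Every pad and corner coordinate produced by
#: the layout and repair code is a multiple of this.
GRID_STEP = 10


class GridPoint(NamedTuple):
    x: int
    y: int


def snap(v: float, step: int = GRID_STEP) -> int:
    """Round ``v`` to the nearest multiple of ``step``."""
    return int(round(v / step)) * step


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open: [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValueError(f"inverted rectangle {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains(self, p: GridPoint) -> bool:
        return self.x0 <= p.x < self.x1 and self.y0 <= p.y < self.y1

    def contains_strict(self, p: GridPoint) -> bool:
        """True iff ``p`` is in the open interior (boundary excluded)."""
        return self.x0 < p.x < self.x1 and self.y0 < p.y < self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (self.x0 <= other.x0 and other.x1 <= self.x1
                and self.y0 <= other.y0 and other.y1 <= self.y1)

    def intersects(self, other: "Rect") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)

    def translate(self, dx: int, dy: int) -> "Rect":
        return Rect(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def inflate(self, d: int) -> "Rect":
        return Rect(self.x0 - d, self.y0 - d, self.x1 + d, self.y1 + d)

    @staticmethod
    def bounding(rects: Iterable["Rect"]) -> "Rect":
        rects = list(rects)
        if not rects:
            return Rect(0, 0, 0, 0)
        return Rect(min(r.x0 for r in rects), min(r.y0 for r in rects),
                    max(r.x1 for r in rects), max(r.y1 for r in rects))


@dataclass(frozen=True)
class Segment:
    """Directed drawn segment between two distinct grid points."""

    a: GridPoint
    b: GridPoint

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"degenerate segment at {self.a}")

    @property
    def direction(self) -> tuple[int, int]:
        dx, dy = self.b.x - self.a.x, self.b.y - self.a.y

        def sgn(v: int) -> int:
            return (v > 0) - (v < 0)

        return (sgn(dx), sgn(dy))

    def length_l1(self) -> int:
        return abs(self.b.x - self.a.x) + abs(self.b.y - self.a.y)


def is_orthogonal(s: Segment) -> bool:
    """True iff the segment is axis-aligned (horizontal or vertical)."""
    return s.a.x == s.b.x or s.a.y == s.b.y


def antiparallel(s1: Segment, s2: Segment) -> bool:
    """True iff the direction vectors point exactly opposite ways."""
    d1, d2 = s1.direction, s2.direction
    return d1[0] == -d2[0] and d1[1] == -d2[1]


class OverlapKind(enum.Enum):
    NONE = "none"
    SHARED_ENDPOINT = "shared_endpoint"
    COLLINEAR_INTERVAL = "collinear_interval"
    CROSSING = "crossing"


@dataclass(frozen=True)
class OverlapReport:
    kind: OverlapKind
    #: a point for shared_endpoint / crossing, a (GridPoint, GridPoint)
    #: interval with positive length for collinear_interval, None otherwise
    where: object = None


_NO_OVERLAP = OverlapReport(OverlapKind.NONE)


def _as_interval(s: Segment) -> tuple[int, str, int, int]:
    """Normalize an orthogonal segment to (line coord, axis, lo, hi)."""
    if s.a.y == s.b.y:
        return (s.a.y, "h", min(s.a.x, s.b.x), max(s.a.x, s.b.x))
    return (s.a.x, "v", min(s.a.y, s.b.y), max(s.a.y, s.b.y))


def _endpoints(s: Segment) -> frozenset[GridPoint]:
    return frozenset((s.a, s.b))


def segments_overlap(s1: Segment, s2: Segment) -> OverlapReport:
    """Classify how two orthogonal segments interact.

    Returns ``none`` for disjoint segments, ``collinear_interval`` when they
    share a run of positive length, ``shared_endpoint`` when they meet at a
    point that is an endpoint of both (a legal tree corner), and ``crossing``
    for any other single-point contact (a true crossing or a T-junction).
    Symmetric in its arguments.  Diagonal inputs are handled by a generic
    point intersection and flagged as crossing when they meet.
    """
    if not (is_orthogonal(s1) and is_orthogonal(s2)):
        return _generic_intersection(s1, s2)

    c1, ax1, lo1, hi1 = _as_interval(s1)
    c2, ax2, lo2, hi2 = _as_interval(s2)

    if ax1 == ax2:
        if c1 != c2:
            return _NO_OVERLAP
        lo, hi = max(lo1, lo2), min(hi1, hi2)
        if lo > hi:
            return _NO_OVERLAP
        if lo < hi:
            if ax1 == "h":
                iv = (GridPoint(lo, c1), GridPoint(hi, c1))
            else:
                iv = (GridPoint(c1, lo), GridPoint(c1, hi))
            return OverlapReport(OverlapKind.COLLINEAR_INTERVAL, iv)
        p = GridPoint(lo, c1) if ax1 == "h" else GridPoint(c1, lo)
    else:
        if ax1 == "v":  # make s1 horizontal for the test below
            (c1, lo1, hi1), (c2, lo2, hi2) = (c2, lo2, hi2), (c1, lo1, hi1)
        # now: horizontal at y=c1 over x in [lo1,hi1]; vertical at x=c2 over
        # y in [lo2,hi2]
        if not (lo1 <= c2 <= hi1 and lo2 <= c1 <= hi2):
            return _NO_OVERLAP
        p = GridPoint(c2, c1)

    if p in _endpoints(s1) and p in _endpoints(s2):
        return OverlapReport(OverlapKind.SHARED_ENDPOINT, p)
    return OverlapReport(OverlapKind.CROSSING, p)


def _generic_intersection(s1: Segment, s2: Segment) -> OverlapReport:
    """Exact rational intersection test for possibly-diagonal segments."""
    p, r = s1.a, (s1.b.x - s1.a.x, s1.b.y - s1.a.y)
    q, s = s2.a, (s2.b.x - s2.a.x, s2.b.y - s2.a.y)
    cross = r[0] * s[1] - r[1] * s[0]
    qp = (q.x - p.x, q.y - p.y)
    if cross == 0:
        # parallel; report collinear overlap only if on the same line with a
        # shared run (rare for the inputs this package produces)
        if qp[0] * r[1] - qp[1] * r[0] != 0:
            return _NO_OVERLAP
        # project onto r
        def t_of(pt: GridPoint) -> int:
            return (pt.x - p.x) * r[0] + (pt.y - p.y) * r[1]

        lo1, hi1 = sorted((0, r[0] * r[0] + r[1] * r[1]))
        lo2, hi2 = sorted((t_of(s2.a), t_of(s2.b)))
        lo, hi = max(lo1, lo2), min(hi1, hi2)
        if lo > hi:
            return _NO_OVERLAP
        if lo == hi:
            pt = s2.a if t_of(s2.a) == lo else s2.b
            if pt in _endpoints(s1) and pt in _endpoints(s2):
                return OverlapReport(OverlapKind.SHARED_ENDPOINT, pt)
            return OverlapReport(OverlapKind.CROSSING, pt)
        return OverlapReport(OverlapKind.COLLINEAR_INTERVAL, (s1.a, s1.b))
    t_num = qp[0] * s[1] - qp[1] * s[0]
    u_num = qp[0] * r[1] - qp[1] * r[0]
    if cross < 0:
        t_num, u_num, cross = -t_num, -u_num, -cross
    if not (0 <= t_num <= cross and 0 <= u_num <= cross):
        return _NO_OVERLAP
    px = p.x + t_num * r[0] / cross
    py = p.y + t_num * r[1] / cross
    pt = GridPoint(int(px), int(py)) if px == int(px) and py == int(py) else None
    if pt is not None and pt in _endpoints(s1) and pt in _endpoints(s2):
        return OverlapReport(OverlapKind.SHARED_ENDPOINT, pt)
    return OverlapReport(OverlapKind.CROSSING, pt if pt is not None else GridPoint(snap(px, 1), snap(py, 1)))


# ---------------------------------------------------------------------------
# Link trees


class LinkTree:
    """Per-source routing tree.

    Tree nodes are opaque integer ids (so two corners may transiently share
    coordinates while a tree is malformed); each id carries a grid point.
    The root is the source's launch pad; every leaf pad corresponds to
    exactly one outbound (target, sign) link of the source.
    """

    def __init__(self, source: str, root: GridPoint):
        self.source = source
        self._next_id = 0
        self.points: dict[int, GridPoint] = {}
        self.parent: dict[int, int] = {}
        #: (target node id, sign) -> tree node id of the landing pad
        self.leaf_ids: dict[tuple[str, object], int] = {}
        self.root_id = self._new_node(root)

    # -- construction -----------------------------------------------------
    def _new_node(self, p: GridPoint) -> int:
        nid = self._next_id
        self._next_id += 1
        self.points[nid] = p
        return nid

    def add_corner(self, parent_id: int, p: GridPoint) -> int:
        if parent_id not in self.points:
            raise KeyError(f"unknown tree node {parent_id}")
        nid = self._new_node(p)
        self.parent[nid] = parent_id
        return nid

    def add_leaf(self, parent_id: int, pad: GridPoint, target: str, sign) -> int:
        key = (target, sign)
        if key in self.leaf_ids:
            raise ValueError(f"duplicate leaf for {key!r}")
        nid = self.add_corner(parent_id, pad)
        self.leaf_ids[key] = nid
        return nid

    # -- views ------------------------------------------------------------
    @property
    def root(self) -> GridPoint:
        return self.points[self.root_id]

    @property
    def corners(self) -> set[GridPoint]:
        return set(self.points.values())

    @property
    def leaves(self) -> dict[tuple[str, object], GridPoint]:
        """(target, sign) -> landing pad."""
        return {key: self.points[nid] for key, nid in self.leaf_ids.items()}

    def children(self, nid: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == nid)

    def edges(self) -> Iterator[tuple[int, int]]:
        """(parent id, child id) pairs in deterministic order."""
        for c in sorted(self.parent):
            yield self.parent[c], c

    def segments(self) -> list[Segment]:
        out = []
        for p, c in self.edges():
            a, b = self.points[p], self.points[c]
            if a != b:
                out.append(Segment(a, b))
        return out

    def edge_segments(self) -> list[tuple[int, int, Segment]]:
        out = []
        for p, c in self.edges():
            a, b = self.points[p], self.points[c]
            if a != b:
                out.append((p, c, Segment(a, b)))
        return out

    def node_degree(self, nid: int) -> int:
        d = len(self.children(nid))
        if nid in self.parent:
            d += 1
        return d

    def validate_structure(self) -> None:
        """Raise ValueError if the tree invariants are broken."""
        for c, p in self.parent.items():
            if p not in self.points:
                raise ValueError(f"dangling parent pointer {c}->{p}")
        # connectivity / acyclicity: walk each node to the root
        for nid in self.points:
            seen = set()
            cur = nid
            while cur != self.root_id:
                if cur in seen or cur not in self.parent:
                    raise ValueError(f"node {nid} not connected to root")
                seen.add(cur)
                cur = self.parent[cur]
        for key, nid in self.leaf_ids.items():
            if nid not in self.points:
                raise ValueError(f"leaf pad for {key!r} missing from tree")

    def copy(self) -> "LinkTree":
        t = LinkTree.__new__(LinkTree)
        t.source = self.source
        t._next_id = self._next_id
        t.points = dict(self.points)
        t.parent = dict(self.parent)
        t.leaf_ids = dict(self.leaf_ids)
        t.root_id = self.root_id
        return t


def tree_targets(tree: LinkTree) -> set[tuple[str, object]]:
    """The (target id, sign) pairs the tree carries — the connectivity
    quantity every geometry tool must conserve."""
    return set(tree.leaf_ids)


def _tree_adjacent(tree: LinkTree, e1: tuple[int, int], e2: tuple[int, int]) -> bool:
    return bool({e1[0], e1[1]} & {e2[0], e2[1]})


def is_well_formed(tree: LinkTree) -> list[OverlapReport]:
    """All-pairs overlap audit of a tree's segments.

    Empty iff no pair of distinct segments shares a collinear run and no
    pair meets except at a shared tree corner.  Coincident corners of
    unrelated branches and T-junctions both count as problems: either makes
    a click on that point ambiguous.
    """
    problems: list[OverlapReport] = []
    edges = tree.edge_segments()
    for i in range(len(edges)):
        p1, c1, s1 = edges[i]
        for j in range(i + 1, len(edges)):
            p2, c2, s2 = edges[j]
            rep = segments_overlap(s1, s2)
            if rep.kind is OverlapKind.NONE:
                continue
            if rep.kind is OverlapKind.SHARED_ENDPOINT:
                if _tree_adjacent(tree, (p1, c1), (p2, c2)):
                    continue
                problems.append(rep)
            else:
                problems.append(rep)
    return problems
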