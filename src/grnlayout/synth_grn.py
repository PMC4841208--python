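"""Seeded synthetic GRN generator.

Emulates the structure of a simulated regulatory network used to exercise
overlay-driven layout: a small set of "control" genes that regulate each
other sparsely and drive everything else, and a large population of
"target" genes that have inputs only.  Each target is wired to exactly one
*input signature* — a sampled subset of the control genes — so targets
fall into natural groups by their combination of inputs, which is exactly
the module structure the overlay generator turns into One-Box modules.

Also provides ``perturb_tree``, a seeded simulation of a user dragging
link-tree corners and segments into malformed configurations, used to
exercise the orthogonalization and repair tools.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterable, Optional

from .core_model import GrnModel, NodeKind, Sign
from .grid_geometry import GRID_STEP, GridPoint, LinkTree, Rect


class InfeasibleParamsError(ValueError):
    pass


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs.  Defaults give the desk-scale test network used
    throughout the suite: 6 control genes, 60 targets in 6 signature
    groups, signatures of 1-3 controls, mostly activating links."""

    n_control: int = 6
    p_control_edge: float = 0.3
    n_targets: int = 60
    n_signatures: int = 6
    signature_size_range: tuple[int, int] = (1, 3)
    #: probabilities of (promote, repress) for each generated link sign
    sign_mix: tuple[float, float] = (0.7, 0.3)
    seed: int = 42

    def validate(self) -> None:
        lo, hi = self.signature_size_range
        if not (1 <= lo <= hi <= max(self.n_control, 1)):
            raise InfeasibleParamsError(
                f"signature sizes {self.signature_size_range} infeasible "
                f"for {self.n_control} control genes")
        n_subsets = sum(math.comb(self.n_control, k)
                        for k in range(lo, hi + 1))
        if self.n_signatures > n_subsets:
            raise InfeasibleParamsError(
                f"{self.n_signatures} signatures requested but only "
                f"{n_subsets} distinct control subsets of sizes "
                f"{lo}..{hi} exist")
        if self.n_control < 1:
            raise InfeasibleParamsError("need at least one control gene")
        if not 0.0 <= self.p_control_edge <= 1.0:
            raise InfeasibleParamsError("p_control_edge must be in [0, 1]")
        if (len(self.sign_mix) != 2 or any(p < 0 for p in self.sign_mix)
                or sum(self.sign_mix) <= 0):
            raise InfeasibleParamsError("sign_mix must be two non-negative "
                                        "weights")
        if self.n_targets < 0 or self.n_signatures < 0:
            raise InfeasibleParamsError("counts must be non-negative")
        if self.n_targets and not self.n_signatures:
            raise InfeasibleParamsError("targets need at least one signature")


def _draw_sign(rng: random.Random, mix: tuple[float, float]) -> Sign:
    p_promote = mix[0] / (mix[0] + mix[1])
    return Sign.PROMOTE if rng.random() < p_promote else Sign.REPRESS


def generate_grn(params: Optional[SynthParams] = None) -> GrnModel:
    """Generate a control/target network, reproducible from the seed.

    Every control gene ends with out-degree >= 1 (a control not covered by
    any signature or control-control edge gets one edge to the next
    control in cyclic order); every target has out-degree 0 and is wired
    to exactly one sampled signature.
    """
    params = params or SynthParams()
    params.validate()
    rng = random.Random(params.seed)

    cw = len(str(params.n_control))
    controls = [f"C{i + 1:0{cw}d}" for i in range(params.n_control)]
    tw = len(str(max(params.n_targets, 1)))
    targets = [f"T{i + 1:0{tw}d}" for i in range(params.n_targets)]

    model = GrnModel(f"synth-grn-seed{params.seed}")
    for c in controls:
        model.add_node(c, kind=NodeKind.GENE)
    for t in targets:
        model.add_node(t, kind=NodeKind.GENE)

    # sparse control-control wiring
    for ci in controls:
        for cj in controls:
            if ci != cj and rng.random() < params.p_control_edge:
                model.add_link(ci, cj, _draw_sign(rng, params.sign_mix))

    # sample distinct signatures (subsets of controls)
    lo, hi = params.signature_size_range
    all_subsets = [tuple(sorted(s))
                   for k in range(lo, hi + 1)
                   for s in itertools.combinations(controls, k)]
    signatures = sorted(rng.sample(all_subsets, params.n_signatures))

    # wire targets: the first n_signatures targets cover every signature,
    # the rest draw uniformly
    for i, t in enumerate(targets):
        sig = signatures[i] if i < len(signatures) \
            else signatures[rng.randrange(len(signatures))]
        for c in sig:
            model.add_link(c, t, _draw_sign(rng, params.sign_mix))

    # guarantee out-degree >= 1 for every control
    for i, c in enumerate(controls):
        if not model.outbound_links(c):
            if len(controls) == 1:
                raise InfeasibleParamsError(
                    "single control gene with no possible outbound link")
            other = controls[(i + 1) % len(controls)]
            model.add_link(c, other, _draw_sign(rng, params.sign_mix))
    return model


def generate_overlay_from_signatures(model: GrnModel):
    """Build a One-Box overlay from a control/target model.

    Controls (out-degree >= 1) split into at most two control modules;
    targets (out-degree 0) get one module per distinct input signature.
    Module links cover every inter-module node-level link, so the overlay
    validates with no blocking problems.  Provisional boxes are placed on
    a coarse grid (controls on top) with pairwise distinct centers.
    """
    from .overlay_layout import ModuleLink, NetworkModule, NetworkOverlay

    controls = [n for n in sorted(model.nodes) if model.outbound_links(n)]
    targets = [n for n in sorted(model.nodes) if not model.outbound_links(n)]

    groups: list[tuple[str, list[str]]] = []
    if controls:
        if len(controls) >= 2:
            half = (len(controls) + 1) // 2
            groups.append(("controls-1", controls[:half]))
            groups.append(("controls-2", controls[half:]))
        else:
            groups.append(("controls-1", controls))
    by_sig: dict[tuple[str, ...], list[str]] = {}
    for t in targets:
        by_sig.setdefault(model.input_signature(t), []).append(t)
    for i, sig in enumerate(sorted(by_sig)):
        groups.append((f"targets-{i + 1}", by_sig[sig]))

    # provisional boxes: row-major grid, three per row, distinct centers
    modules = []
    bw, bh, gx, gy = 400, 200, 100, 100
    for i, (name, members) in enumerate(groups):
        row, col = divmod(i, 3)
        x0 = col * (bw + gx) + row * GRID_STEP  # stagger: distinct x centers
        y0 = row * (bh + gy) + col * GRID_STEP  # stagger: distinct y centers
        modules.append(NetworkModule(name=name, members=frozenset(members),
                                     box=Rect(x0, y0, x0 + bw, y0 + bh)))

    member_of = {m: g for g, members in groups for m in members}
    pair_set = set()
    for l in model.sorted_links():
        a, b = member_of[l.source], member_of[l.target]
        if a != b:
            pair_set.add((a, b))
    box_of = {m.name: m.box for m in modules}
    links = []
    for a, b in sorted(pair_set):
        links.append(ModuleLink(source=a, target=b,
                                waypoints=_center_elbow(box_of[a], box_of[b])))
    return NetworkOverlay(name="signature-modules", modules=modules,
                          module_links=links, intensity=0.15)


def _center_elbow(a: Rect, b: Rect) -> tuple[GridPoint, ...]:
    """Orthogonal two-leg polyline between box centers, grid-snapped."""
    ax = int(round((a.x0 + a.x1) / 2 / GRID_STEP)) * GRID_STEP
    ay = int(round((a.y0 + a.y1) / 2 / GRID_STEP)) * GRID_STEP
    bx = int(round((b.x0 + b.x1) / 2 / GRID_STEP)) * GRID_STEP
    by = int(round((b.y0 + b.y1) / 2 / GRID_STEP)) * GRID_STEP
    pts = [GridPoint(ax, ay)]
    if bx != ax:
        pts.append(GridPoint(bx, ay))
    if by != ay:
        pts.append(GridPoint(bx, by))
    if len(pts) == 1:
        pts.append(GridPoint(bx + GRID_STEP, by))
    return tuple(pts)


# ---------------------------------------------------------------------------
# Simulated drags


_OFFSETS = [d * GRID_STEP for d in (-3, -2, -1, 1, 2, 3)]


def perturb_tree(tree: LinkTree, n_drags: int, seed: int,
                 avoid: Iterable[Rect] = (),
                 kinds: tuple[str, ...] = ("corner", "segment")) -> LinkTree:
    """Simulate a user quickly dragging tree corners and segments around.

    Each drag either displaces one interior corner by a random grid offset
    (usually diagonalizing its two incident segments) or shifts a whole
    interior segment perpendicular to itself (staying orthogonal but
    typically creating overlaps/crossings).  Root and leaf pads never
    move; topology and targets are preserved.  ``avoid`` rectangles model
    the user dropping corners into whitespace: a drag that would land a
    corner strictly inside one is re-drawn.  ``kinds`` restricts the drag
    repertoire: corner moves are always diagonal (both offsets non-zero),
    segment shifts stay orthogonal but typically create overlaps and
    crossings.  Reproducible from the seed.
    """
    rng = random.Random(seed)
    out = tree.copy()
    avoid = list(avoid)
    fixed = set(out.leaf_ids.values()) | {out.root_id}
    movable = sorted(set(out.points) - fixed)
    if not movable or not kinds:
        return out
    for _ in range(n_drags):
        kind = kinds[rng.randrange(len(kinds))]
        if kind == "corner":
            _drag_corner(out, rng, movable, avoid)
        else:
            _drag_segment(out, rng, movable, fixed, avoid)
    return out


def _clear(p: GridPoint, avoid: list[Rect]) -> bool:
    return not any(r.contains_strict(p) for r in avoid)


def _drag_corner(tree: LinkTree, rng: random.Random,
                 movable: list[int], avoid: list[Rect]) -> None:
    nid = movable[rng.randrange(len(movable))]
    p = tree.points[nid]
    for _ in range(20):
        q = GridPoint(p.x + rng.choice(_OFFSETS), p.y + rng.choice(_OFFSETS))
        if q != p and _clear(q, avoid):
            tree.points[nid] = q
            return


def _drag_segment(tree: LinkTree, rng: random.Random,
                  movable: list[int], fixed: set[int],
                  avoid: list[Rect]) -> None:
    movable_set = set(movable)
    edges = [(p, c) for p, c in tree.edges()
             if p in movable_set and c in movable_set
             and tree.points[p] != tree.points[c]]
    if not edges:
        return
    p, c = edges[rng.randrange(len(edges))]
    a, b = tree.points[p], tree.points[c]
    horizontal = a.y == b.y
    for _ in range(20):
        d = rng.choice(_OFFSETS)
        if horizontal:
            na, nb = GridPoint(a.x, a.y + d), GridPoint(b.x, b.y + d)
        else:
            na, nb = GridPoint(a.x + d, a.y), GridPoint(b.x + d, b.y)
        if _clear(na, avoid) and _clear(nb, avoid):
            tree.points[p], tree.points[c] = na, nb
            return
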