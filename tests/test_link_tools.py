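import pytest

import grnlayout as gl
from grnlayout.grid_geometry import (GridPoint, LinkTree, Rect, Segment,
                                     is_orthogonal, is_well_formed,
                                     tree_targets)
from grnlayout.link_tools import (AggregateGeometryError, NoSolutionError,
                                  ObstacleSet, orthogonalize_all,
                                  orthogonalize_tree, repair_all, repair_tree)

P = GridPoint


def diagonal_tree():
    t = LinkTree("S", P(0, 0))
    t.add_leaf(t.root_id, P(30, 20), "B", gl.Sign.PROMOTE)
    return t


def path_reversals(t):
    """Count 180-degree fold-backs along root-to-leaf paths."""
    n = 0
    for p, c in t.edges():
        a, b = t.points[p], t.points[c]
        if a == b:
            continue
        for g in t.children(c):
            gp = t.points[g]
            if gp == b:
                continue
            if Segment(b, a).direction == Segment(b, gp).direction:
                n += 1
    return n


class TestOrthogonalize:
    def test_single_diagonal_splits_horizontal_first(self):
        fixed = orthogonalize_tree(diagonal_tree())
        pts = sorted(fixed.points.values())
        assert pts == [P(0, 0), P(30, 0), P(30, 20)]

    def test_already_orthogonal_is_identity(self, stacked):
        src = sorted(stacked.trees)[0]
        tree = stacked.trees[src]
        fixed = orthogonalize_tree(tree)
        assert sorted(fixed.points.values()) == sorted(tree.points.values())
        assert fixed.parent == tree.parent

    def test_blocked_horizontal_elbow_falls_back_to_vertical(self):
        # a footprint across the horizontal-first leg at y=0
        obs = ObstacleSet(node_rects=[Rect(0, -20, 40, 10)])
        fixed = orthogonalize_tree(diagonal_tree(), obs)
        assert P(0, 20) in fixed.points.values()
        for seg in fixed.segments():
            assert not obs.segment_blocked(seg)

    def test_fully_walled_target_is_no_solution(self):
        # a tall wall between root and pad that no in-region route clears
        obs = ObstacleSet(node_rects=[Rect(10, -2000, 30, 2000)])
        with pytest.raises(NoSolutionError) as exc:
            orthogonalize_tree(diagonal_tree(), obs)
        assert exc.value.segment is not None

    def test_preexisting_u_turn_preserved_and_corners_retained(self):
        # a U-shaped detour (down, right, up) guides placement: the tool
        # keeps the gross feature and the existing corners
        t = LinkTree("S", P(0, 0))
        a = t.add_corner(t.root_id, P(0, 40))
        b = t.add_corner(a, P(60, 40))
        c = t.add_corner(b, P(60, 13))  # slightly off-axis corner
        t.add_leaf(c, P(100, 10), "B", gl.Sign.PROMOTE)
        fixed = orthogonalize_tree(t)
        kept = {P(0, 40), P(60, 40)}
        assert kept <= set(fixed.points.values())
        assert len(fixed.points) >= len(t.points)
        assert path_reversals(fixed) == 0

    def test_no_new_reversals_and_obstacle_free_over_seeded_drags(
            self, stacked, node_obstacles):
        """Orthogonalization of corner-dragged trees: all segments become
        orthogonal, targets conserved, obstacles respected, no new
        180-degree turns, idempotent."""
        rects = node_obstacles.node_rects
        sources = sorted(stacked.trees)
        for rep in range(60):
            src = sources[rep % len(sources)]
            t = gl.perturb_tree(stacked.trees[src], n_drags=4,
                                seed=1000 + rep, avoid=rects,
                                kinds=("corner",))
            pre = path_reversals(t)
            fixed = orthogonalize_tree(t, node_obstacles)
            assert tree_targets(fixed) == tree_targets(t)
            for s in fixed.segments():
                assert is_orthogonal(s)
                assert not node_obstacles.segment_blocked(s)
            assert path_reversals(fixed) <= pre
            again = orthogonalize_tree(fixed, node_obstacles)
            assert sorted(again.points.values()) \
                == sorted(fixed.points.values())


class TestRepair:
    def test_collinear_branches_merged_into_trunk(self):
        # two branches drawn on top of each other over a shared interval
        t = LinkTree("S", P(0, 0))
        a1 = t.add_corner(t.root_id, P(0, 30))
        b1 = t.add_corner(a1, P(60, 30))
        t.add_leaf(b1, P(60, 60), "B", gl.Sign.PROMOTE)
        a2 = t.add_corner(t.root_id, P(0, 30))
        b2 = t.add_corner(a2, P(90, 30))
        t.add_leaf(b2, P(90, 60), "C", gl.Sign.PROMOTE)
        assert is_well_formed(t) != []
        fixed = repair_tree(t)
        assert is_well_formed(fixed) == []
        assert tree_targets(fixed) == tree_targets(t)
        # shared run merged: the root now has a single trunk child
        assert len(fixed.children(fixed.root_id)) == 1

    def test_clean_tree_unchanged_geometry(self, stacked):
        src = sorted(stacked.trees)[0]
        tree = stacked.trees[src]
        fixed = repair_tree(tree)
        assert is_well_formed(fixed) == []
        assert tree_targets(fixed) == tree_targets(tree)
        again = repair_tree(fixed)
        assert sorted(again.points.values()) == sorted(fixed.points.values())

    def test_no_solution_names_blocked_targets(self):
        t = LinkTree("S", P(0, 0))
        t.add_leaf(t.root_id, P(100, 0), "B", gl.Sign.PROMOTE)
        obs = ObstacleSet(node_rects=[Rect(40, -3000, 60, 3000)])
        with pytest.raises(NoSolutionError) as exc:
            repair_tree(t, obs)
        assert exc.value.blocked_targets == ["B"]

    def test_seeded_drag_repair_restores_well_formedness(
            self, stacked, node_obstacles):
        """The drag-then-clean-up shortcut: every seeded perturbation of a
        stacked tree repairs to well-formed with targets preserved."""
        rects = node_obstacles.node_rects
        sources = sorted(stacked.trees)
        for rep in range(40):
            src = sources[rep % len(sources)]
            t = gl.perturb_tree(stacked.trees[src], n_drags=6,
                                seed=2000 + rep, avoid=rects)
            fixed = repair_tree(t, node_obstacles)
            assert is_well_formed(fixed) == []
            assert tree_targets(fixed) == tree_targets(t)
            for s in fixed.segments():
                assert is_orthogonal(s)


class TestLayoutWideTools:
    def test_all_orthogonal_layout_is_identity(self, synth_model, stacked):
        out = orthogonalize_all(stacked)
        for s in stacked.trees:
            assert sorted(out.trees[s].points.values()) \
                == sorted(stacked.trees[s].points.values())

    def test_repair_all_on_perturbed_layout(self, synth_model, stacked,
                                            node_obstacles):
        perturbed = gl.Layout(placements=dict(stacked.placements),
                              trees={s: gl.perturb_tree(
                                  t, 3, seed=77 + i,
                                  avoid=node_obstacles.node_rects)
                                  for i, (s, t) in
                                  enumerate(sorted(stacked.trees.items()))},
                              bounds=stacked.bounds,
                              meta=dict(stacked.meta))
        fixed = repair_all(perturbed)
        for s, tree in fixed.trees.items():
            assert is_well_formed(tree) == []
            assert tree_targets(tree) == tree_targets(stacked.trees[s])
        from conftest import cross_tree_collinear_overlaps
        assert cross_tree_collinear_overlaps(fixed) == 0

    def test_aggregate_error_continues_past_failures(self):
        m = gl.GrnModel("m")
        for n in ("A", "B", "C", "D"):
            m.add_node(n)
        m.add_link("A", "B", gl.Sign.PROMOTE)
        m.add_link("C", "D", gl.Sign.PROMOTE)
        lay = gl.stacked_layout(m)
        # bury B's pad deep inside a blocking footprint: unreachable
        pad = lay.trees["A"].leaves[("B", gl.Sign.PROMOTE)]
        wall = gl.Rect(pad.x - 50, pad.y - 50, pad.x + 50, pad.y + 50)
        broken = gl.Layout(placements=dict(lay.placements),
                           trees={s: t.copy()
                                  for s, t in lay.trees.items()},
                           bounds=lay.bounds, meta=dict(lay.meta))
        broken.placements["WALL"] = wall
        with pytest.raises(AggregateGeometryError) as exc:
            repair_all(broken)
        assert "A" in exc.value.errors
        # C's tree was still processed
        assert is_well_formed(exc.value.layout.trees["C"]) == []
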