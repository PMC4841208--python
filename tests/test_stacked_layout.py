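import pytest

import grnlayout as gl
from grnlayout.stacked_layout import (StackedParams, assign_rows,
                                      landing_pads, launch_pad,
                                      order_targets_by_source, place_rows,
                                      stacked_layout)

from conftest import assert_layout_invariants


def model_from(links, extra_nodes=(), kinds=None):
    m = gl.GrnModel("m")
    kinds = kinds or {}
    for a, b in links:
        for n in (a, b):
            m.add_node(n, kind=kinds.get(n, gl.NodeKind.GENE))
    for n in extra_nodes:
        m.add_node(n, kind=kinds.get(n, gl.NodeKind.GENE))
    for a, b in links:
        m.add_link(a, b, gl.Sign.PROMOTE)
    return m


class TestOrdering:
    def test_single_signature_group(self):
        m = model_from([("A", "B"), ("A", "C")])
        assert order_targets_by_source(m) == ["A", "B", "C"]

    def test_signature_groups_sorted_by_signature(self):
        # C has inputs {A,B}, D has inputs {A}: group {A} precedes {A,B}
        m = model_from([("A", "C"), ("B", "C"), ("A", "D")])
        assert order_targets_by_source(m) == ["A", "B", "D", "C"]

    def test_no_links_gives_id_order(self):
        m = model_from([], extra_nodes=["c", "a", "b"])
        assert order_targets_by_source(m) == ["a", "b", "c"]

    def test_non_gene_feeder_pulled_adjacent_to_its_gene(self):
        m = model_from([("bub", "G2"), ("A", "G1"), ("A", "G2")],
                       kinds={"bub": gl.NodeKind.BUBBLE})
        ordered = order_targets_by_source(m)
        assert ordered.index("bub") + 1 == ordered.index("G2")


class TestRows:
    @pytest.mark.parametrize("n,max_row,expected", [
        (45, 20, [20, 20, 5]),
        (1, 20, [1]),
        (20, 20, [20]),
    ])
    def test_row_major_fill(self, n, max_row, expected):
        rows = assign_rows([f"n{i:03d}" for i in range(n)],
                           StackedParams(max_row_size=max_row))
        assert [len(r) for r in rows] == expected
        assert [x for r in rows for x in r] == [f"n{i:03d}" for i in range(n)]

    def test_feeder_kept_with_its_gene_across_break(self):
        m = model_from([("bub", "G")], kinds={"bub": gl.NodeKind.BUBBLE})
        for i in range(3):
            m.add_node(f"x{i}")
        ordered = ["x0", "x1", "x2", "bub", "G"]
        rows = assign_rows(ordered, StackedParams(max_row_size=4), m)
        (row_of,) = [i for i, r in enumerate(rows) if "bub" in r]
        assert "G" in rows[row_of]


class TestPlacement:
    def test_track_band_reserved_above_row(self):
        m = model_from([("A", "B")])
        rows = [["A", "B"]]
        placements, meta = place_rows(rows, StackedParams(), m)
        # one source -> one track; the row sits one track pitch down
        assert meta["track_bands"][0] == (0, 10)
        assert all(r.y0 >= 10 for r in placements.values())

    def test_zero_links_zero_height_bands(self):
        m = model_from([], extra_nodes=["A", "B"])
        placements, meta = place_rows([["A"], ["B"]], StackedParams(), m)
        assert meta["track_bands"] == [(0, 0),
                                       (20 + StackedParams().row_gap,
                                        20 + StackedParams().row_gap)]
        assert meta["spine_band"] == (0, 0)

    def test_one_spine_column_and_track_per_row_for_shared_source(self):
        # A feeds a node in each of two rows: one spine column, one track
        # in each row's band
        m = model_from([("A", "B"), ("A", "C")])
        rows = [["A", "B"], ["C"]]
        placements, meta = place_rows(rows, StackedParams(), m)
        assert meta["spine_band"] == (0, 10)
        assert meta["band_sources"] == [["A"], ["A"]]
        assert [b[1] - b[0] for b in meta["track_bands"]] == [10, 10]

    def test_no_footprint_enters_reserved_bands(self, stacked):
        sx0, sx1 = stacked.meta["spine_band"]
        for r in stacked.placements.values():
            assert r.x0 >= sx1
            for y0, y1 in stacked.meta["track_bands"]:
                assert r.y1 <= y0 or r.y0 >= y1


class TestRouting:
    def test_same_row_route_is_three_orthogonal_segments(self):
        m = model_from([("A", "B")])
        lay = stacked_layout(m)
        (tree,) = lay.trees.values()
        segs = tree.segments()
        assert len(segs) == 3
        assert all(gl.is_orthogonal(s) for s in segs)
        # up from the launch pad, across the track, drop onto B
        pad = tree.leaves[("B", gl.Sign.PROMOTE)]
        assert pad.y == lay.placements["B"].y0
        assert tree.root == launch_pad(lay.placements["A"])

    def test_cross_row_route_passes_through_spine(self):
        m = model_from([(f"S{i}", f"T{j}") for i in range(2)
                        for j in range(4)])
        lay = stacked_layout(m, StackedParams(max_row_size=3))
        sx = lay.meta["spine_x"]
        for s, tree in lay.trees.items():
            xs = {p.x for p in tree.points.values()}
            # the source's own spine column is used, no other source's
            assert sx[s] in xs
            for other, x in sx.items():
                if other != s:
                    assert x not in xs

    def test_ten_targets_share_one_trunk(self):
        m = model_from([("A", f"T{i}") for i in range(10)])
        lay = stacked_layout(m, StackedParams(max_row_size=20))
        (tree,) = lay.trees.values()
        assert gl.is_well_formed(tree) == []
        pads = set(tree.leaves.values())
        drops = [s for s in tree.segments()
                 if s.a.x == s.b.x and s.b in pads and s.b.y > s.a.y]
        assert len(drops) == 10

    def test_horizontal_runs_confined_to_track_bands(self, stacked):
        bands = stacked.meta["track_bands"]
        for tree in stacked.trees.values():
            for seg in tree.segments():
                if seg.a.y == seg.b.y:
                    assert any(y0 <= seg.a.y < y1 or seg.a.y == y1 - 10
                               for y0, y1 in bands if y1 > y0), seg

    def test_inter_row_verticals_confined_to_spine(self, stacked):
        sx0, sx1 = stacked.meta["spine_band"]
        row_spans = []
        tops = stacked.meta["row_tops"]
        bands = stacked.meta["track_bands"]
        for i, top in enumerate(tops):
            row_spans.append((bands[i][0], top + 20))
        for tree in stacked.trees.values():
            for seg in tree.segments():
                if seg.a.x != seg.b.x:
                    continue
                lo, hi = sorted((seg.a.y, seg.b.y))
                within_one_row = any(lo >= y0 and hi <= y1
                                     for y0, y1 in row_spans)
                if not within_one_row:
                    assert sx0 <= seg.a.x < sx1, seg


class TestLayoutContract:
    def test_two_node_chain(self):
        m = model_from([("A", "B")])
        lay = stacked_layout(m)
        assert len(lay.trees) == 1
        assert_layout_invariants(m, lay)

    def test_full_synth_invariants(self, synth_model, stacked):
        assert_layout_invariants(synth_model, stacked)
        for row in stacked.meta["rows"]:
            assert len(row) <= 20

    def test_determinism_byte_identical_json(self, synth_model):
        p = gl.StackedParams(max_row_size=20)
        a = gl.layout_to_json(synth_model, stacked_layout(synth_model, p))
        b = gl.layout_to_json(synth_model, stacked_layout(synth_model, p))
        assert a == b

    def test_subset_layout(self, synth_model):
        subset = {"C1", "C2", "T01"}
        lay = stacked_layout(synth_model, node_subset=subset)
        assert set(lay.placements) == subset
        sub = synth_model.submodel(subset)
        assert_layout_invariants(sub, lay)

    def test_subset_without_sources_has_no_trees(self, synth_model):
        lay = stacked_layout(synth_model, node_subset={"T01", "T02"})
        assert lay.trees == {}

    def test_empty_subset_rejected(self, synth_model):
        with pytest.raises(ValueError):
            stacked_layout(synth_model, node_subset=set())

    def test_genes_first_adjacency_in_rows(self):
        m = model_from([("bub", "G1"), ("A", "G1"), ("A", "G2")],
                       kinds={"bub": gl.NodeKind.BUBBLE})
        lay = stacked_layout(m)
        for row in lay.meta["rows"]:
            if "bub" in row:
                assert abs(row.index("bub") - row.index("G1")) == 1
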