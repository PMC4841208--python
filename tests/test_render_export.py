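import json
import random
import re

import pytest

import grnlayout as gl
from grnlayout.grid_geometry import GridPoint
from grnlayout.render_export import (DrawLayer, Scene, hit_test, parse_json,
                                     render_model, serialize_json, shape_hit,
                                     validate_scene_doc, write_svg)

P = GridPoint


def brute_force_hit(scene, p):
    """Independent oracle: test every shape of every group directly (no
    bounds pre-filter), topmost layer wins, area tie-break."""
    for layer in sorted(scene.layers, reverse=True):
        hits = []
        for g in scene.layers[layer]:
            if any(shape_hit(s, p) for s in g.shapes):
                area = sum(b.width * b.height for b in g.bounds)
                hits.append((area, g.element_id))
        if hits:
            hits.sort()
            return hits[0][1]
    return None


class TestRenderModel:
    def test_single_node_renders_group_label_and_selection(self):
        m = gl.GrnModel("m")
        m.add_node("geneA")
        lay = gl.stacked_layout(m)
        scene = render_model(m, lay)
        nodes = scene.layers[DrawLayer.NODES]
        labels = scene.layers[DrawLayer.LABELS]
        assert [g.element_id for g in nodes] == ["geneA"]
        assert [g.element_id for g in labels] == ["geneA"]
        assert nodes[0].selected_shapes
        assert scene.layers[DrawLayer.LINKS] == []

    def test_sign_glyphs_arrow_vs_bar(self, tiny_model):
        lay = gl.stacked_layout(tiny_model)
        scene = render_model(tiny_model, lay)
        by_id = {g.element_id: g for g in scene.layers[DrawLayer.LINKS]}
        # A promotes B (arrowhead path) and represses C (bar line)
        a_types = [s.type for s in by_id["link:A"].shapes]
        assert "path" in a_types          # arrowhead for the promote leaf
        bars = [s for s in by_id["link:A"].shapes
                if s.type == "line" and dict(s.style).get("stroke") == "repress"]
        assert bars                        # bar for the repress leaf

    def test_modules_land_in_underlay_below_links(self, synth_model,
                                                  overlay_result):
        layout, new_ov = overlay_result
        scene = render_model(synth_model, layout, new_ov)
        under = scene.layers[DrawLayer.UNDERLAY_MODULES]
        assert len(under) == len(new_ov.modules)
        assert int(DrawLayer.UNDERLAY_MODULES) < int(DrawLayer.LINKS)

    def test_unplaced_element_errors(self, tiny_model):
        lay = gl.stacked_layout(tiny_model, node_subset={"A", "B"})
        with pytest.raises(KeyError):
            render_model(tiny_model, lay)

    def test_bounds_cover_every_shape(self, scene):
        from grnlayout.render_export import _shape_bounds
        for g in scene.groups():
            cover = list(g.bounds)
            for s in g.shapes:
                sb = _shape_bounds(s)
                assert any(b.intersects(sb) or b.contains_rect(sb)
                           for b in cover), (g.element_id, s)


class TestHitTest:
    def test_point_inside_node(self, synth_model, stacked, scene):
        r = stacked.placements["C1"]
        p = P((r.x0 + r.x1) // 2, (r.y0 + r.y1) // 2)
        assert hit_test(scene, p) == "C1"

    def test_point_on_link_segment_within_half_width(self):
        m = gl.GrnModel("m")
        m.add_node("A"); m.add_node("B")
        m.add_link("A", "B", gl.Sign.PROMOTE)
        lay = gl.stacked_layout(m)
        scene = render_model(m, lay)
        seg = lay.trees["A"].segments()[1]  # the horizontal track run
        mid = P((seg.a.x + seg.b.x) // 2, (seg.a.y + seg.b.y) // 2)
        assert hit_test(scene, mid) == "link:A"
        off = P(mid.x, mid.y + 2)  # still within half the stroke width
        assert hit_test(scene, off) == "link:A"
        far = P(mid.x, mid.y + 5)
        assert hit_test(scene, far) != "link:A"

    def test_empty_space_is_none(self, scene):
        assert hit_test(scene, P(scene.bounds.x1 - 1,
                                 scene.bounds.y1 - 1)) is None

    def test_agreement_with_brute_force_oracle(self, scene):
        rng = random.Random(11)
        b = scene.bounds
        disagreements = 0
        for _ in range(2000):
            p = P(rng.randint(b.x0, b.x1), rng.randint(b.y0, b.y1))
            if hit_test(scene, p) != brute_force_hit(scene, p):
                disagreements += 1
        assert disagreements == 0

    def test_bounds_soundness(self, scene):
        rng = random.Random(13)
        b = scene.bounds
        groups = scene.groups()
        for _ in range(2000):
            p = P(rng.randint(b.x0, b.x1), rng.randint(b.y0, b.y1))
            for g in groups:
                if any(shape_hit(s, p) for s in g.shapes):
                    assert any(r.contains(p) for r in g.bounds), g.element_id


class TestSerialization:
    def test_empty_model_document_has_all_layers(self):
        m = gl.GrnModel("empty")
        scene = render_model(m, gl.stacked_layout(m))
        doc = json.loads(serialize_json(scene))
        assert [l["ordinal"] for l in doc["layers"]] == list(range(6))
        assert all(l["groups"] == [] for l in doc["layers"])

    def test_schema_valid_and_round_trip(self, scene):
        text = serialize_json(scene)
        assert validate_scene_doc(json.loads(text)) == []
        assert parse_json(text) == scene

    def test_serialize_twice_byte_identical(self, scene):
        assert serialize_json(scene) == serialize_json(scene)

    def test_validator_flags_broken_documents(self, scene):
        doc = json.loads(serialize_json(scene))
        doc["layers"][2]["groups"][0]["shapes"][0]["geometry"] = {"bogus": 1}
        assert validate_scene_doc(doc) != []
        assert validate_scene_doc({"schema_version": 1}) != []


class TestSvg:
    def test_single_rect_shape(self):
        m = gl.GrnModel("m")
        m.add_node("box1", kind=gl.NodeKind.BOX)
        scene = render_model(m, gl.stacked_layout(m))
        svg = write_svg(scene)
        assert svg.count("<rect ") == 1

    def test_layer_order_matches_ordinals(self, synth_model, overlay_result):
        layout, new_ov = overlay_result
        svg = write_svg(render_model(synth_model, layout, new_ov))
        positions = [svg.index(f'id="layer-{layer.name.lower()}"')
                     for layer in sorted(DrawLayer)]
        assert positions == sorted(positions)

    def test_element_count_matches_shape_count(self, scene):
        svg = write_svg(scene)
        nshapes = sum(len(g.shapes) for g in scene.groups())
        nelems = len(re.findall(r"<(line|rect|ellipse|path|text) ", svg))
        assert nelems == nshapes

    def test_selection_shapes_only_when_requested(self, scene):
        plain = write_svg(scene)
        assert "layer-selection-active" not in plain
        sel = write_svg(scene, selection={"C1"})
        assert "layer-selection-active" in sel
        assert sel.count("<") > plain.count("<")
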