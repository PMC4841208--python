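from dataclasses import replace

import pytest

import grnlayout as gl
from grnlayout.grid_geometry import GridPoint, Rect
from grnlayout.overlay_layout import (ModuleLink, NetworkModule,
                                      NetworkOverlay, OverlayValidationError,
                                      overlay_driven_layout,
                                      resize_module_to_bounds,
                                      validate_overlay)

from conftest import assert_layout_invariants

P = GridPoint


def two_module_setup():
    m = gl.GrnModel("m")
    for n in ("A", "B", "X", "Y"):
        m.add_node(n)
    m.add_link("A", "B", gl.Sign.PROMOTE)
    m.add_link("A", "X", gl.Sign.PROMOTE)
    m.add_link("X", "Y", gl.Sign.REPRESS)
    ov = NetworkOverlay(
        name="ov",
        modules=[NetworkModule("M1", frozenset({"A", "B"}),
                               box=Rect(0, 0, 200, 100)),
                 NetworkModule("M2", frozenset({"X", "Y"}),
                               box=Rect(300, 200, 500, 300))],
        module_links=[ModuleLink("M1", "M2",
                                 waypoints=(P(100, 50), P(400, 50),
                                            P(400, 250)))])
    return m, ov


class TestValidateOverlay:
    def test_valid_overlay_passes(self):
        m, ov = two_module_setup()
        assert [p for p in validate_overlay(m, ov) if p.blocking] == []

    def test_intra_module_only_links_need_no_module_links(self):
        m = gl.GrnModel("m")
        for n in ("A", "B"):
            m.add_node(n)
        m.add_link("A", "B", gl.Sign.PROMOTE)
        ov = NetworkOverlay("ov", [NetworkModule("M", frozenset({"A", "B"}),
                                                 box=Rect(0, 0, 100, 100))])
        assert validate_overlay(m, ov) == []

    def test_missing_module_link_reported(self):
        m, ov = two_module_setup()
        stripped = NetworkOverlay(ov.name, ov.modules, [], ov.intensity)
        problems = [p for p in validate_overlay(m, stripped) if p.blocking]
        assert [p.kind for p in problems] == ["missing-module-link"]
        assert "M1" in problems[0].detail and "M2" in problems[0].detail

    def test_crooked_module_link_reported(self):
        m, ov = two_module_setup()
        crooked = NetworkOverlay(
            ov.name, ov.modules,
            [replace(ov.module_links[0],
                     waypoints=(P(100, 50), P(400, 250)))])
        problems = [p for p in validate_overlay(m, crooked) if p.blocking]
        assert [p.kind for p in problems] == ["crooked-link"]

    def test_unassigned_node_is_warning_only(self):
        m, ov = two_module_setup()
        m.add_node("stray")
        problems = validate_overlay(m, ov)
        assert [p.kind for p in problems] == ["unassigned-node"]
        assert not problems[0].blocking

    def test_duplicate_assignment_blocks(self):
        m, ov = two_module_setup()
        dup = NetworkOverlay(ov.name, ov.modules + [
            NetworkModule("M3", frozenset({"A"}), box=Rect(600, 0, 700, 100))],
            ov.module_links)
        kinds = {p.kind for p in validate_overlay(m, dup) if p.blocking}
        assert "duplicate-assignment" in kinds


class TestResize:
    def test_box_wraps_member_with_padding(self):
        m, ov = two_module_setup()
        lay = gl.stacked_layout(m)
        resized = resize_module_to_bounds(ov.modules[0], lay)
        for nid in ("A", "B"):
            assert resized.box.contains_rect(lay.placements[nid])
        assert resize_module_to_bounds(resized, lay).box == resized.box

    def test_unplaced_member_errors(self):
        m, ov = two_module_setup()
        lay = gl.stacked_layout(m, node_subset={"A", "B"})
        with pytest.raises(KeyError):
            resize_module_to_bounds(ov.modules[1], lay)


class TestOverlayDrivenLayout:
    def test_validation_failure_aborts_with_problems(self):
        m, ov = two_module_setup()
        stripped = NetworkOverlay(ov.name, ov.modules, [], ov.intensity)
        with pytest.raises(OverlayValidationError) as exc:
            overlay_driven_layout(m, stripped)
        assert any(p.kind == "missing-module-link" for p in exc.value.problems)

    def test_two_module_layout_satisfies_contract(self):
        m, ov = two_module_setup()
        layout, new_ov = overlay_driven_layout(m, ov)
        assert_layout_invariants(m, layout)
        boxes = {mm.name: mm.box for mm in new_ov.modules}
        members = {mm.name: mm.members for mm in new_ov.modules}
        for name, box in boxes.items():
            for nid in members[name]:
                assert box.contains_rect(layout.placements[nid])

    def test_center_orderings_preserved(self, synth_model, signature_overlay,
                                        overlay_result):
        layout, new_ov = overlay_result
        old = {m.name: m.box.center for m in signature_overlay.modules}
        new = {m.name: m.box.center for m in new_ov.modules}
        names = sorted(old)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for axis in (0, 1):
                    if old[a][axis] < old[b][axis]:
                        assert new[a][axis] < new[b][axis], (a, b, axis)
                    elif old[a][axis] > old[b][axis]:
                        assert new[a][axis] > new[b][axis], (a, b, axis)

    def test_boxes_disjoint_and_contain_members(self, overlay_result):
        layout, new_ov = overlay_result
        boxes = [(m.name, m.box) for m in new_ov.modules]
        for i, (an, a) in enumerate(boxes):
            for bn, b in boxes[i + 1:]:
                assert not a.intersects(b), (an, bn)
        for m in new_ov.modules:
            for nid in m.members:
                assert m.box.contains_rect(layout.placements[nid]), nid

    def test_full_synth_layout_invariants(self, synth_model, overlay_result):
        layout, _ = overlay_result
        assert_layout_invariants(synth_model, layout)

    def test_per_module_sublayouts_satisfy_stacked_contract(
            self, synth_model, overlay_result):
        layout, _ = overlay_result
        for name, info in sorted(layout.meta["modules"].items()):
            sub = info["sublayout"]
            subm = synth_model.submodel(info["members"])
            assert_layout_invariants(subm, sub)
            for row in sub.meta["rows"]:
                assert len(row) <= 20

    def test_target_modules_are_signature_pure(self, synth_model,
                                               overlay_result):
        """Each target module's members share a single input signature —
        the defining structure of the overlay-driven drawing."""
        _, new_ov = overlay_result
        for m in new_ov.modules:
            if not m.name.startswith("targets-"):
                continue
            sigs = {synth_model.input_signature(n) for n in m.members}
            assert len(sigs) == 1, m.name

    def test_unassigned_nodes_get_pseudo_module(self):
        m, ov = two_module_setup()
        m.add_node("stray")
        layout, new_ov = overlay_driven_layout(m, ov)
        assert "stray" in layout.placements
        assert "unassigned" not in {mm.name for mm in new_ov.modules}

    def test_determinism(self, synth_model, signature_overlay):
        l1, _ = overlay_driven_layout(synth_model, signature_overlay)
        l2, _ = overlay_driven_layout(synth_model, signature_overlay)
        assert gl.layout_to_json(synth_model, l1) \
            == gl.layout_to_json(synth_model, l2)
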