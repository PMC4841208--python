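import pytest

import grnlayout as gl


@pytest.fixture(scope="session")
def synth_model():
    """The desk-scale control/target network used across the suite."""
    return gl.generate_grn(gl.SynthParams(seed=42))


@pytest.fixture(scope="session")
def stacked(synth_model):
    return gl.stacked_layout(synth_model, gl.StackedParams(max_row_size=20))


@pytest.fixture(scope="session")
def node_obstacles(stacked):
    return gl.ObstacleSet(node_rects=[stacked.placements[n]
                                      for n in sorted(stacked.placements)])


@pytest.fixture(scope="session")
def signature_overlay(synth_model):
    return gl.generate_overlay_from_signatures(synth_model)


@pytest.fixture(scope="session")
def overlay_result(synth_model, signature_overlay):
    return gl.overlay_driven_layout(synth_model, signature_overlay)


@pytest.fixture(scope="session")
def scene(synth_model, stacked):
    return gl.render_model(synth_model, stacked)


@pytest.fixture
def tiny_model():
    m = gl.GrnModel("tiny")
    for n in ("A", "B", "C"):
        m.add_node(n)
    m.add_link("A", "B", gl.Sign.PROMOTE)
    m.add_link("A", "C", gl.Sign.REPRESS)
    m.add_link("B", "C", gl.Sign.PROMOTE)
    return m


def cross_tree_collinear_overlaps(layout):
    """Count collinear overlaps between segments of *different* trees."""
    from grnlayout.grid_geometry import OverlapKind, segments_overlap
    tagged = []
    for s in sorted(layout.trees):
        tagged.extend((s, seg) for seg in layout.trees[s].segments())
    n = 0
    for i in range(len(tagged)):
        for j in range(i + 1, len(tagged)):
            if tagged[i][0] == tagged[j][0]:
                continue
            rep = segments_overlap(tagged[i][1], tagged[j][1])
            if rep.kind is OverlapKind.COLLINEAR_INTERVAL:
                n += 1
    return n


def assert_layout_invariants(model, layout):
    """The full Layout invariant suite: disjoint footprints, orthogonal
    well-formed trees, no cross-tree collinear overlap, connectivity
    conservation, bounds containment."""
    placed = sorted(layout.placements)
    for i, a in enumerate(placed):
        for b in placed[i + 1:]:
            assert not layout.placements[a].intersects(layout.placements[b]), \
                f"footprints of {a} and {b} overlap"
    for s in sorted(layout.trees):
        tree = layout.trees[s]
        tree.validate_structure()
        for seg in tree.segments():
            assert gl.is_orthogonal(seg), (s, seg)
        assert gl.is_well_formed(tree) == [], s
        expected = {(l.target, l.sign) for l in model.outbound_links(s)
                    if l.target in layout.placements}
        assert gl.tree_targets(tree) == expected, s
    assert cross_tree_collinear_overlaps(layout) == 0
    for nid, r in layout.placements.items():
        assert layout.bounds.contains_rect(r), nid
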