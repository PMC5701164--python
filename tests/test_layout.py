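"""Layout engine: closed-form placement, refactoring closure, diffs, counts."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from padcad.fixtures import SplitterConfig, first_stage_channels, make_case_study
from padcad.layout import (
    LayoutError,
    check_alignment,
    count_elements,
    diff_positions,
    insert_adhesive_holes,
    refactor,
    resolve,
)
from padcad.model import (
    Attach,
    DesignNode,
    DeviceDesign,
    LayerSpec,
    Material,
    Placement,
    Shape,
)

from conftest import expected_moved_ids, random_tree_design


def _single(design, node_id):
    return next(e for e in resolve(design) if e.node_id == node_id)


def _chain(*nodes):
    for parent, child in zip(nodes, nodes[1:]):
        parent.children.append(child)
    return nodes[0]


def _design(*roots, layers=None):
    design = DeviceDesign(layers=layers or [LayerSpec(1, Material.PAPER)])
    design.roots.extend(roots)
    return design


# --- resolve ----------------------------------------------------------------

def test_single_root_at_origin(one_circle):
    assert _single(one_circle, "c").center == (0.0, 0.0)


@pytest.mark.parametrize(
    "angle, expected",
    [
        (0.0, (10.0, 0.0)),
        (240.0, (-5.0, -8.6602540378)),  # 10·(cos 240°, sin 240°)
    ],
)
def test_center_attach_is_polar_offset(angle, expected):
    root = DesignNode("p", Shape.circle(4.0))
    root.children.append(DesignNode("q", Shape.circle(2.0), Placement(angle, 10.0)))
    center = _single(_design(root), "q").center
    assert center == pytest.approx(expected, abs=1e-9)


def test_abut_channel_spans_rim_to_far_end():
    """A channel of length l abutting a circle of diameter d starts at the
    rim and ends at d/2 + l from the parent center."""
    root = DesignNode("p", Shape.circle(8.0))
    root.children.append(
        DesignNode("ch", Shape.rect(6.0, 1.0), Placement(0.0, 0.0, Attach.ABUT)))
    element = _single(_design(root), "ch")
    assert element.center == pytest.approx((4.0 + 3.0, 0.0))
    assert element.polygon.bounds[0] == pytest.approx(4.0)   # near edge at the rim
    assert element.polygon.bounds[2] == pytest.approx(10.0)  # far end at d/2 + l


def test_abut_distance_adds_a_gap():
    root = DesignNode("p", Shape.circle(8.0))
    root.children.append(
        DesignNode("z", Shape.circle(2.0), Placement(90.0, 1.5, Attach.ABUT)))
    assert _single(_design(root), "z").center == pytest.approx((0.0, 4 + 1 + 1.5))


def test_cross_layer_distance_zero_is_centered():
    layers = [LayerSpec(1, Material.PAPER), LayerSpec(2, Material.PAPER)]
    root = DesignNode("p", Shape.circle(4.0), Placement(30.0, 7.0), layer=1)
    root.children.append(DesignNode("q", Shape.circle(3.0), layer=2))
    elements = resolve(_design(root, layers=layers))
    by_id = {e.node_id: e for e in elements}
    assert by_id["q"].center == by_id["p"].center
    assert by_id["q"].cross_layer


def test_resolution_is_translation_equivariant():
    rng = random.Random(7)
    design = random_tree_design(rng, 10)
    vx, vy = 13.25, -4.5
    shifted = refactor(design)
    root = shifted.roots[0]
    # re-aim the (circle) root at its old center plus v
    d0 = float(root.placement.distance)
    a0 = math.radians(root.placement.angle)
    cx, cy = d0 * math.cos(a0) + vx, d0 * math.sin(a0) + vy
    root.placement = Placement(math.degrees(math.atan2(cy, cx)), math.hypot(cx, cy))
    for before, after in zip(resolve(design), resolve(shifted)):
        assert after.center[0] - before.center[0] == pytest.approx(vx, abs=1e-9)
        assert after.center[1] - before.center[1] == pytest.approx(vy, abs=1e-9)


def test_every_node_yields_exactly_one_element():
    design = make_case_study("splitter3D")
    normalized = insert_adhesive_holes(design)
    ids = [n.id for n in normalized.nodes()]
    assert sorted(ids) == sorted(e.node_id for e in resolve(design))


# --- adhesive hole auto-generation ------------------------------------------

def test_holes_inserted_on_traversed_adhesive():
    layers = [LayerSpec(1, Material.PAPER), LayerSpec(2, Material.ADHESIVE),
              LayerSpec(3, Material.PAPER)]
    root = DesignNode("top", Shape.circle(4.0), layer=1)
    root.children.append(DesignNode("bottom", Shape.circle(3.0), layer=3))
    elements = resolve(_design(root, layers=layers))
    holes = [e for e in elements if e.layer == 2]
    assert [h.node_id for h in holes] == ["bottom@adh2"]
    assert holes[0].material is Material.ADHESIVE
    assert holes[0].center == (0.0, 0.0)
    # hole diameter = min of the connected flow widths
    assert holes[0].polygon.bounds[2] == pytest.approx(1.5)


def test_hole_ids_stable_across_refactoring():
    design = make_case_study("splitter3D")
    edited = refactor(design, parameter_edits={"seg": 9.0})
    assert {e.node_id for e in resolve(design)} == {e.node_id for e in resolve(edited)}


# --- refactor + diff --------------------------------------------------------

def test_empty_edit_is_identity():
    design = make_case_study("splitter3D")
    diff = diff_positions(resolve(design), resolve(refactor(design)))
    assert diff.moved == frozenset()


def test_unknown_edit_targets_raise():
    design = make_case_study("splitter1L")
    with pytest.raises(KeyError):
        refactor(design, parameter_edits={"nope": 1.0})
    with pytest.raises(KeyError):
        refactor(design, node_edits={"ghost": {"distance": 1.0}})


def test_diff_requires_matching_id_sets(one_circle):
    other = DeviceDesign(layers=[LayerSpec(1, Material.PAPER)])
    other.roots.append(DesignNode("different", Shape.circle(5.0)))
    with pytest.raises(LayoutError, match="id sets differ"):
        diff_positions(resolve(one_circle), resolve(other))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 12))
def test_refactoring_closure_random_trees(seed, n_nodes):
    """A distance edit moves exactly the edited node, its subtree, and the
    subtree's adhesive holes — verified against a brute-force traversal."""
    rng = random.Random(seed)
    design = random_tree_design(rng, n_nodes)
    target = rng.choice([n.id for n in design.nodes()][1:] or ["n0"])
    node = design.node(target)
    edited = refactor(design, node_edits={
        target: {"distance": float(node.placement.distance) + 5.0}})
    diff = diff_positions(resolve(design), resolve(edited))
    assert diff.moved == frozenset(expected_moved_ids(design, target))


def test_untouched_elements_bit_identical():
    design = make_case_study("splitter3D")
    channel = first_stage_channels(design)[0]
    edited = refactor(design, node_edits={channel: {"length": 9.0}})
    before = {e.node_id: e.center for e in resolve(design)}
    after = {e.node_id: e.center for e in resolve(edited)}
    moved = expected_moved_ids(design, channel)
    for node_id, center in after.items():
        if node_id not in moved:
            assert center == before[node_id]  # exact, not approx


# --- element counts ---------------------------------------------------------

def test_empty_design_counts_zero():
    per_layer, total = count_elements(DeviceDesign())
    assert per_layer == {} and total == 0


@pytest.mark.parametrize("samples", [1, 2, 3, 4])
def test_splitter_counts_match_closed_form(samples):
    """Two binary stages + one 1→4 stage: (s, s, 5s, 2s, 10s, 4s, 36s, 16s, 16s)."""
    design = make_case_study("splitter3D", samples=samples)
    per_layer, total = count_elements(design)
    expected = [samples * k for k in (1, 1, 5, 2, 10, 4, 36, 16, 16)]
    assert [per_layer[i] for i in sorted(per_layer)] == expected
    assert total == 91 * samples


def test_splitter_config_rejects_bad_fanout():
    with pytest.raises(ValueError):
        SplitterConfig(stages=(2, 5))
    with pytest.raises(ValueError):
        SplitterConfig(samples=0)


# --- cross-layer alignment --------------------------------------------------

def test_alignment_clean_on_fixture_at_zero_tolerance():
    assert check_alignment(resolve(make_case_study("splitter3D")), 0.0) == []


def test_deliberately_offset_cross_layer_child_reported():
    layers = [LayerSpec(1, Material.PAPER), LayerSpec(2, Material.PAPER)]
    root = DesignNode("p", Shape.circle(4.0), layer=1)
    root.children.append(DesignNode("q", Shape.circle(3.0), Placement(0.0, 2.0), layer=2))
    misses = check_alignment(resolve(_design(root, layers=layers)), 1e-6)
    assert [(m.parent_id, m.child_id) for m in misses] == [("p", "q")]
    assert misses[0].offset == pytest.approx(2.0)
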