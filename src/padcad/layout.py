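"""Layout engine: relative tree -> absolute per-layer geometry.

This is the core of the tool. ``resolve`` walks the node forest and
turns every relative placement into an absolute footprint in mm; a
parameter or node edit followed by re-resolution repositions exactly
the edited nodes and their descendants across every layer, which is
what makes designs cheap to refactor. ``diff_positions`` measures that
propagation, ``count_elements`` tallies objects per layer, and
``check_alignment`` asserts the cross-layer registration guarantee that
multi-layer stacked devices depend on for reproducible capillary flow.

Conventions: math is y-up, angles CCW from +x; circles are
polygonalized at ``CIRCLE_SEGMENTS`` chords; rectangles and text boxes
are oriented lengthwise along their placement angle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import shapely.geometry as sgeom

from ._expr import eval_expression
from .model import (
    Attach,
    DesignNode,
    DeviceDesign,
    Material,
    Placement,
    Role,
    Shape,
    ShapeKind,
    validate,
)

__all__ = [
    "CIRCLE_SEGMENTS",
    "DIFF_TOLERANCE",
    "LayoutError",
    "Misalignment",
    "PositionDiff",
    "ResolvedElement",
    "check_alignment",
    "count_elements",
    "diff_positions",
    "insert_adhesive_holes",
    "refactor",
    "resolve",
    "to_jsonl",
]

CIRCLE_SEGMENTS = 128   # chords per circle footprint
DIFF_TOLERANCE = 1e-6   # mm; layout is closed-form, true motion dwarfs float noise
TEXT_ADVANCE = 0.6      # nominal glyph advance as a fraction of text height


class LayoutError(ValueError):
    pass


@dataclass
class ResolvedElement:
    """A node's absolute footprint on its layer after layout."""

    node_id: str
    parent_id: str | None
    layer: int
    material: Material
    role: Role
    center: tuple[float, float]
    polygon: sgeom.Polygon
    orientation: float        # degrees; lengthwise axis for rects, 0 for circles
    distance: float           # resolved placement distance, mm
    cross_layer: bool         # parent on a different layer

    @property
    def footprint(self) -> list[tuple[float, float]]:
        return list(self.polygon.exterior.coords)


# ---------------------------------------------------------------------------
# shape geometry helpers

def _dims(shape: Shape, params: dict[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    if shape.kind is ShapeKind.CIRCLE:
        out["diameter"] = eval_expression(shape.diameter, params)
    elif shape.kind is ShapeKind.RECT:
        out["length"] = eval_expression(shape.length, params)
        out["width"] = eval_expression(shape.width, params)
    elif shape.kind is ShapeKind.TEXT:
        h = eval_expression(shape.height, params)
        out["length"] = max(TEXT_ADVANCE * h * len(shape.text or " "), 1e-6)
        out["width"] = h
    return out


def _support(shape: Shape, dims: dict[str, float], orientation: float, theta: float) -> float:
    """Half-extent of the shape, from its anchor, along direction *theta* (deg)."""
    if shape.kind is ShapeKind.CIRCLE:
        return dims["diameter"] / 2.0
    if shape.kind in (ShapeKind.RECT, ShapeKind.TEXT):
        delta = math.radians(theta - orientation)
        return abs(math.cos(delta)) * dims["length"] / 2.0 + abs(math.sin(delta)) * dims["width"] / 2.0
    if shape.kind is ShapeKind.POLYGON:
        ux, uy = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        return max(x * ux + y * uy for x, y in shape.vertices)
    raise LayoutError(f"unsupported shape kind {shape.kind}")


def _footprint(shape: Shape, dims: dict[str, float], center: tuple[float, float],
               orientation: float) -> sgeom.Polygon:
    cx, cy = center
    if shape.kind is ShapeKind.CIRCLE:
        r = dims["diameter"] / 2.0
        pts = [
            (cx + r * math.cos(2 * math.pi * k / CIRCLE_SEGMENTS),
             cy + r * math.sin(2 * math.pi * k / CIRCLE_SEGMENTS))
            for k in range(CIRCLE_SEGMENTS)
        ]
        return sgeom.Polygon(pts)
    if shape.kind in (ShapeKind.RECT, ShapeKind.TEXT):
        hl, hw = dims["length"] / 2.0, dims["width"] / 2.0
        phi = math.radians(orientation + (shape.rotation if shape.kind is ShapeKind.TEXT else 0.0))
        c, s = math.cos(phi), math.sin(phi)
        corners = [(-hl, -hw), (hl, -hw), (hl, hw), (-hl, hw)]
        return sgeom.Polygon([(cx + x * c - y * s, cy + x * s + y * c) for x, y in corners])
    if shape.kind is ShapeKind.POLYGON:
        return sgeom.Polygon([(cx + x, cy + y) for x, y in shape.vertices])
    raise LayoutError(f"unsupported shape kind {shape.kind}")


# ---------------------------------------------------------------------------
# adhesive hole auto-generation

def _flow_width(shape: Shape, params: dict[str, float]) -> float:
    dims = _dims(shape, params)
    if shape.kind is ShapeKind.CIRCLE:
        return dims["diameter"]
    if shape.kind is ShapeKind.RECT:
        return dims["width"]
    if shape.kind is ShapeKind.POLYGON:
        xs = [v[0] for v in shape.vertices]
        ys = [v[1] for v in shape.vertices]
        return min(max(xs) - min(xs), max(ys) - min(ys))
    return 1.0


def insert_adhesive_holes(design: DeviceDesign) -> DeviceDesign:
    """Return a copy with through-holes inserted on traversed adhesive layers.

    Every flow connection that hops two layers across a declared
    adhesive layer gets a circular hole node on that layer, diameter
    ``min(parent flow width, child flow width)`` unless overridden by
    ``defaults.hole_diameter``. Hole ids are derived from the child id
    (``<child>@adh<N>``) so they are stable across refactoring; the
    hole takes over the child's placement and the child re-attaches to
    the hole at distance 0, leaving all absolute positions unchanged.
    """
    design = copy.deepcopy(design)
    adhesive = {spec.index for spec in design.layers if spec.material is Material.ADHESIVE}
    params = design.parameters

    def visit(node: DesignNode) -> None:
        for i, child in enumerate(list(node.children)):
            if (
                abs(child.layer - node.layer) == 2
                and (mid := (child.layer + node.layer) // 2) in adhesive
                and node.shape.role is Role.FLOW
                and child.shape.role is Role.FLOW
            ):
                d = design.defaults.hole_diameter
                if d is None:
                    d = min(_flow_width(node.shape, params), _flow_width(child.shape, params))
                hole = DesignNode(
                    f"{child.id}@adh{mid}",
                    Shape.circle(d),
                    replace(child.placement),
                    layer=mid,
                    children=[child],
                )
                child.placement = Placement(angle=child.placement.angle, distance=0.0)
                node.children[i] = hole
            visit(child)

    for root in design.roots:
        visit(root)
    return design


# ---------------------------------------------------------------------------
# resolution

def resolve(design: DeviceDesign, *, insert_holes: bool = True) -> list[ResolvedElement]:
    """Resolve the relative tree to absolute footprints, in pre-order.

    Same-layer ``attach=center`` children sit at
    ``parent_center + distance * (cos θ, sin θ)``; ``attach=abut``
    children touch the parent boundary along θ (a channel of length ℓ
    abutting a circle of diameter d spans from the rim to d/2 + ℓ),
    with ``distance`` adding an extra gap. A cross-layer child at
    distance 0 is centered exactly on its parent — the alignment
    guarantee for stacked layers.
    """
    violations = validate(design)
    if violations:
        v = violations[0]
        raise LayoutError(f"invalid design: [{v.code}] {v.subject}: {v.message}")
    if insert_holes:
        design = insert_adhesive_holes(design)

    params = design.parameters
    materials = {spec.index: spec.material for spec in design.layers}
    out: list[ResolvedElement] = []

    def visit(node: DesignNode, parent: ResolvedElement | None,
              parent_shape: Shape | None, parent_dims: dict[str, float] | None) -> None:
        theta = node.placement.angle
        dist = eval_expression(node.placement.distance, params)
        dims = _dims(node.shape, params)
        ux, uy = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        if parent is None:
            base = (0.0, 0.0)
            offset = dist
        else:
            base = parent.center
            if node.placement.attach is Attach.ABUT:
                offset = (
                    _support(parent_shape, parent_dims, parent.orientation, theta)
                    + _support(node.shape, dims, theta, theta + 180.0)
                    + dist
                )
            else:
                offset = dist
        center = (base[0] + offset * ux, base[1] + offset * uy)
        orientation = theta if node.shape.kind in (ShapeKind.RECT, ShapeKind.TEXT) else 0.0
        element = ResolvedElement(
            node_id=node.id,
            parent_id=parent.node_id if parent else None,
            layer=node.layer,
            material=materials[node.layer],
            role=node.shape.role,
            center=center,
            polygon=_footprint(node.shape, dims, center, orientation),
            orientation=orientation,
            distance=dist,
            cross_layer=parent is not None and parent.layer != node.layer,
        )
        out.append(element)
        for child in node.children:
            visit(child, element, node.shape, dims)

    for root in design.roots:
        visit(root, None, None, None)
    return out


# ---------------------------------------------------------------------------
# refactoring

_PLACEMENT_PROPS = {"angle", "distance", "attach"}
_SHAPE_PROPS = {"diameter", "length", "width", "height", "rotation", "text"}


def refactor(
    design: DeviceDesign,
    parameter_edits: dict[str, float] | None = None,
    node_edits: dict[str, dict[str, object]] | None = None,
) -> DeviceDesign:
    """Return an edited copy; the original design is left untouched.

    ``parameter_edits`` maps declared parameter names to new values;
    ``node_edits`` maps node ids to property dicts over
    ``angle/distance/attach`` and ``diameter/length/width/height/
    rotation/text``. Re-resolving the result repositions exactly the
    edited nodes and their descendants (cross-layer ones included);
    everything else resolves bit-identically.
    """
    edited = copy.deepcopy(design)
    for name, value in (parameter_edits or {}).items():
        if name not in edited.parameters:
            raise KeyError(f"unknown parameter {name!r}")
        edited.parameters[name] = float(value)
    for node_id, props in (node_edits or {}).items():
        node = edited.node(node_id)  # raises KeyError for unknown ids
        for prop, value in props.items():
            if prop in _PLACEMENT_PROPS:
                if prop == "attach":
                    value = Attach(value)
                setattr(node.placement, prop, value)
                if prop == "angle":
                    node.placement.angle = node.placement.angle % 360.0
            elif prop in _SHAPE_PROPS:
                setattr(node.shape, prop, value)
            else:
                raise KeyError(f"unknown node property {prop!r}")
    return edited


# ---------------------------------------------------------------------------
# diffing and counting

@dataclass
class PositionDiff:
    """Which elements moved between two resolutions, split by material."""

    moved: frozenset[str]
    by_material: dict[str, int] = field(default_factory=dict)
    by_layer: dict[int, int] = field(default_factory=dict)

    @property
    def n_moved(self) -> int:
        return len(self.moved)


def diff_positions(
    before: list[ResolvedElement],
    after: list[ResolvedElement],
    tolerance: float = DIFF_TOLERANCE,
) -> PositionDiff:
    """Ids whose center displaced by more than *tolerance* mm."""
    a = {e.node_id: e for e in before}
    b = {e.node_id: e for e in after}
    if a.keys() != b.keys():
        only_a = sorted(a.keys() - b.keys())[:5]
        only_b = sorted(b.keys() - a.keys())[:5]
        raise LayoutError(f"node-id sets differ (only before: {only_a}, only after: {only_b})")
    moved: set[str] = set()
    by_material: dict[str, int] = {}
    by_layer: dict[int, int] = {}
    for node_id, ea in a.items():
        eb = b[node_id]
        if math.dist(ea.center, eb.center) > tolerance:
            moved.add(node_id)
            by_material[ea.material.value] = by_material.get(ea.material.value, 0) + 1
            by_layer[ea.layer] = by_layer.get(ea.layer, 0) + 1
    return PositionDiff(frozenset(moved), by_material, by_layer)


def count_elements(design: DeviceDesign) -> tuple[dict[int, int], int]:
    """Objects per layer (auto-generated adhesive holes included) and total."""
    per_layer = {spec.index: 0 for spec in design.layers}
    for element in resolve(design):
        per_layer[element.layer] += 1
    return per_layer, sum(per_layer.values())


# ---------------------------------------------------------------------------
# cross-layer alignment check

@dataclass(frozen=True)
class Misalignment:
    parent_id: str
    child_id: str
    offset: float  # mm
    overlapping: bool


def check_alignment(resolved: list[ResolvedElement], tolerance: float = DIFF_TOLERANCE) -> list[Misalignment]:
    """Report cross-layer parent/child pairs that fail registration.

    A pair passes when the footprints overlap and the center offset is
    at most *tolerance*; stacked layers rely on this to keep capillary
    flow reproducible.
    """
    by_id = {e.node_id: e for e in resolved}
    out: list[Misalignment] = []
    for element in resolved:
        if not element.cross_layer or element.parent_id is None:
            continue
        parent = by_id[element.parent_id]
        offset = math.dist(parent.center, element.center)
        overlapping = parent.polygon.intersects(element.polygon)
        if offset > tolerance or not overlapping:
            out.append(Misalignment(parent.node_id, element.node_id, offset, overlapping))
    return out


# ---------------------------------------------------------------------------
# export

def to_jsonl(resolved: list[ResolvedElement]) -> str:
    """One JSON object per element: id, layer, material, center, footprint."""
    import json

    lines = []
    for e in resolved:
        lines.append(json.dumps({
            "nodeId": e.node_id,
            "layer": e.layer,
            "material": e.material.value,
            "role": e.role.value,
            "center": [round(e.center[0], 9), round(e.center[1], 9)],
            "footprint": [[round(x, 6), round(y, 6)] for x, y in e.footprint],
        }))
    return "\n".join(lines) + "\n"
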