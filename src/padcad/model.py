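"""In-memory device model: shapes, relative placements, layers, designs.

A paper-based microfluidic device (µPAD) is modelled as a forest of
nodes. Every node carries a shape with physical dimensions (always in
millimetres internally) and a *relative* placement — an angle and a
distance with respect to its parent — rather than absolute coordinates.
Editing one node or one named parameter therefore repositions the whole
affected branch when the design is re-resolved, across all layers of a
multi-layer stack.

Layer 1 is the top of the stack (the sample-application side). Angles
are degrees, counter-clockwise, 0° along +x, with y pointing up; the
y-down flip happens only when rasters are emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Union

from ._expr import ExpressionError, eval_expression

__all__ = [
    "Attach",
    "Defaults",
    "DesignNode",
    "DeviceDesign",
    "LayerSpec",
    "Material",
    "RenderMode",
    "Role",
    "Shape",
    "ShapeKind",
    "Placement",
    "Violation",
    "validate",
    "MM_PER_INCH",
]

MM_PER_INCH = 25.4

Expr = Union[float, str]  # a literal length in mm, or a parameter expression


class ShapeKind(str, Enum):
    CIRCLE = "circle"
    RECT = "rect"
    POLYGON = "polygon"
    TEXT = "text"


class Role(str, Enum):
    FLOW = "flow"    # hydrophilic: participates in connectivity & buffering
    CUT = "cut"      # outline traced for knife plotter / laser cutter
    DECOR = "decor"  # printed ink only (labels); never fluidic


class Attach(str, Enum):
    CENTER = "center"  # distance measured parent anchor -> child center
    ABUT = "abut"      # child's near boundary touches the parent boundary


class Material(str, Enum):
    PAPER = "paper"
    ADHESIVE = "adhesive"
    MEMBRANE = "membrane"


class RenderMode(str, Enum):
    WAX_FULL = "wax_full"          # white channels on a black background
    WAX_BUFFERED = "wax_buffered"  # shape-fitting black borders (less wax)
    CUT = "cut"                    # stroke outlines for cutting


@dataclass
class Shape:
    """Tagged geometric primitive. Lengths are mm or parameter expressions."""

    kind: ShapeKind
    diameter: Expr | None = None           # circle
    length: Expr | None = None             # rect: extent along the placement angle
    width: Expr | None = None              # rect: extent across it
    vertices: tuple[tuple[float, float], ...] | None = None  # polygon, about anchor
    text: str | None = None
    height: Expr | None = None             # text cap height, mm
    rotation: float = 0.0                  # text rotation, degrees CCW
    font: str | None = None
    role: Role = Role.FLOW

    @classmethod
    def circle(cls, diameter: Expr, role: Role = Role.FLOW) -> "Shape":
        return cls(ShapeKind.CIRCLE, diameter=diameter, role=role)

    @classmethod
    def rect(cls, length: Expr, width: Expr, role: Role = Role.FLOW) -> "Shape":
        return cls(ShapeKind.RECT, length=length, width=width, role=role)

    @classmethod
    def polygon(cls, vertices, role: Role = Role.FLOW) -> "Shape":
        return cls(ShapeKind.POLYGON, vertices=tuple((float(x), float(y)) for x, y in vertices), role=role)

    @classmethod
    def label(cls, text: str, height: Expr = 3.0, rotation: float = 0.0, font: str | None = None) -> "Shape":
        return cls(ShapeKind.TEXT, text=text, height=height, rotation=rotation, font=font, role=Role.DECOR)


def normalize_angle(angle: float) -> float:
    a = math.fmod(float(angle), 360.0)
    return a + 360.0 if a < 0 else a


@dataclass
class Placement:
    """Relative placement: polar offset from the parent plus attachment mode."""

    angle: float = 0.0        # degrees CCW from +x
    distance: Expr = 0.0      # mm, or expression; abut adds it as a gap
    attach: Attach = Attach.CENTER

    def __post_init__(self) -> None:
        self.angle = normalize_angle(self.angle)


@dataclass
class DesignNode:
    id: str
    shape: Shape
    placement: Placement = field(default_factory=Placement)
    layer: int = 1
    children: list["DesignNode"] = field(default_factory=list)
    source_line: int | None = field(default=None, compare=False)

    def add(self, child: "DesignNode") -> "DesignNode":
        self.children.append(child)
        return child

    def walk(self) -> Iterator["DesignNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LayerSpec:
    index: int
    material: Material = Material.PAPER
    render_mode: RenderMode = RenderMode.WAX_BUFFERED


@dataclass
class Defaults:
    border_width: float = 1.5    # shape-fitting wax border, mm
    cut_stroke: float = 0.2      # cut outline stroke, mm
    hole_diameter: float | None = None  # adhesive through-hole override, mm
    canvas_margin: float = 2.0   # padding around the design bbox on renders, mm


@dataclass
class DeviceDesign:
    name: str = "device"
    parameters: dict[str, float] = field(default_factory=dict)
    layers: list[LayerSpec] = field(default_factory=list)
    roots: list[DesignNode] = field(default_factory=list)
    defaults: Defaults = field(default_factory=Defaults)
    sheet: "object | None" = None  # render.SheetSpec, optional script block

    def layer(self, index: int) -> LayerSpec:
        for spec in self.layers:
            if spec.index == index:
                return spec
        raise KeyError(f"layer {index} not declared")

    def nodes(self) -> Iterator[DesignNode]:
        for root in self.roots:
            yield from root.walk()

    def node(self, node_id: str) -> DesignNode:
        for node in self.nodes():
            if node.id == node_id:
                return node
        raise KeyError(f"no node {node_id!r}")

    def parents(self) -> dict[str, str | None]:
        """Map node id -> parent id (None for roots)."""
        out: dict[str, str | None] = {}

        def visit(node: DesignNode, parent: str | None) -> None:
            out[node.id] = parent
            for child in node.children:
                visit(child, node.id)

        for root in self.roots:
            visit(root, None)
        return out


@dataclass(frozen=True)
class Violation:
    code: str
    subject: str   # node id or "layer N"
    message: str


def _check_length(value: Expr | None, params: dict[str, float], what: str,
                  subject: str, out: list[Violation]) -> None:
    if value is None:
        out.append(Violation("missing_dimension", subject, f"{what} is required"))
        return
    try:
        num = eval_expression(value, params)
    except ExpressionError as exc:
        out.append(Violation("bad_expression", subject, f"{what}: {exc}"))
        return
    if num <= 0:
        out.append(Violation("nonpositive_length", subject, f"{what} must be > 0, got {num}"))


def validate(design: DeviceDesign) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions.

    An empty list means the design can be resolved by the layout engine
    without error.
    """
    out: list[Violation] = []
    params = design.parameters

    indices = [spec.index for spec in design.layers]
    if sorted(indices) != list(range(1, len(indices) + 1)):
        out.append(Violation("layer_indices", "layers",
                             f"layer indices must be unique and contiguous from 1, got {indices}"))
    declared = {spec.index: spec for spec in design.layers}

    seen_ids: set[str] = set()
    visiting: set[int] = set()

    def visit(node: DesignNode, parent: DesignNode | None) -> None:
        if id(node) in visiting:
            out.append(Violation("cycle", node.id, "node reachable from itself (aliased subtree)"))
            return
        visiting.add(id(node))
        subject = node.id
        if node.id in seen_ids:
            out.append(Violation("duplicate_id", subject, "node id reused"))
        seen_ids.add(node.id)

        shape = node.shape
        if shape.kind is ShapeKind.CIRCLE:
            _check_length(shape.diameter, params, "circle diameter", subject, out)
        elif shape.kind is ShapeKind.RECT:
            _check_length(shape.length, params, "rect length", subject, out)
            _check_length(shape.width, params, "rect width", subject, out)
        elif shape.kind is ShapeKind.POLYGON:
            verts = shape.vertices or ()
            if len(verts) < 3:
                out.append(Violation("bad_polygon", subject, "polygon needs >= 3 vertices"))
            else:
                import shapely.geometry as sgeom

                if not sgeom.Polygon(verts).is_valid:
                    out.append(Violation("bad_polygon", subject, "polygon is self-intersecting"))
        elif shape.kind is ShapeKind.TEXT:
            if not shape.text:
                out.append(Violation("empty_text", subject, "text shape needs a string"))
            _check_length(shape.height, params, "text height", subject, out)

        try:
            dist = eval_expression(node.placement.distance, params)
            if dist < 0:
                out.append(Violation("negative_distance", subject, f"distance {dist} < 0"))
        except ExpressionError as exc:
            out.append(Violation("bad_expression", subject, f"distance: {exc}"))

        if node.layer not in declared:
            out.append(Violation("undeclared_layer", subject, f"layer {node.layer} not declared"))
        elif parent is not None and parent.layer in declared:
            gap = abs(node.layer - parent.layer)
            if gap > 2:
                out.append(Violation("layer_jump", subject,
                                     f"child on layer {node.layer} too far from parent layer {parent.layer}"))
            elif gap == 2:
                between = declared.get((node.layer + parent.layer) // 2)
                if between is None or between.material is not Material.ADHESIVE:
                    out.append(Violation("layer_jump", subject,
                                         "two-layer hop allowed only across an adhesive layer"))

        for child in node.children:
            visit(child, node)
        visiting.discard(id(node))

    for root in design.roots:
        visit(root, None)
    return out
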