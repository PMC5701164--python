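"""Planar geometry services for wax masks and cut paths.

Flow (hydrophilic) footprints on a layer are grouped into connected
components; each component can be rendered either by flooding the whole
canvas with wax except the flow network (``full_field``), or by drawing
a constant-width, shape-fitting wax border that hugs the component and
uses less wax (``fitted_border``). Cut-mode layers are traced as closed
outline rings (``cut_outline``) suitable for knife plotters and laser
cutters.

All polygon work is done with shapely; circles arrive already
polygonalized (see the layout engine), so every area/length statement
carries a small discretization tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import shapely
import shapely.geometry as sgeom
import shapely.ops
from shapely.geometry.polygon import orient

from .layout import ResolvedElement
from .model import Role

__all__ = [
    "CONNECT_TOLERANCE",
    "CutPath",
    "FlowGroup",
    "GeometryError",
    "connected_components",
    "cut_outline",
    "fitted_border",
    "flow_union",
    "full_field",
    "layer_wax_region",
]

# Footprints closer than this (mm) count as touching: exact-rim abutment of a
# polygonalized circle can leave a sub-micrometre chord gap.
CONNECT_TOLERANCE = 1e-3

BUFFER_QUAD_SEGS = 32  # arc resolution for offset buffering


class GeometryError(ValueError):
    pass


def _close(geom: sgeom.base.BaseGeometry) -> sgeom.base.BaseGeometry:
    """Morphological closing at the connection tolerance.

    Bridges the sub-micrometre chord gaps that exact-rim abutment of
    polygonalized circles leaves, so an abutting chain unions into one
    simple polygon. The boundary perturbation is bounded by
    ``CONNECT_TOLERANCE`` and is sub-pixel at any practical dpi.
    """
    r = CONNECT_TOLERANCE / 2
    return geom.buffer(r, quad_segs=4).buffer(-r, quad_segs=4)


def flow_union(elements: list[ResolvedElement]) -> sgeom.base.BaseGeometry:
    """Union of all flow footprints on a layer, gap-closed.

    Both wax render modes subtract this same union, which is what keeps
    the white (hydrophilic) region identical between them.
    """
    flow = [e.polygon for e in elements if e.role is Role.FLOW]
    if not flow:
        return sgeom.Polygon()
    return _close(shapely.unary_union(flow))


@dataclass
class FlowGroup:
    """A maximal set of mutually connected flow footprints on one layer."""

    members: tuple[str, ...]
    footprint: sgeom.base.BaseGeometry  # union polygon (may carry holes)


def connected_components(elements: list[ResolvedElement]) -> list[FlowGroup]:
    """Partition a layer's flow elements into touching/overlapping groups.

    Zero-area contact counts as connected: an abutting channel/zone pair
    must form one hydrophilic path. Decor elements never participate.
    """
    flow = [e for e in elements if e.role is Role.FLOW]
    n = len(flow)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if flow[i].polygon.distance(flow[j].polygon) <= CONNECT_TOLERANCE:
                parent[find(i)] = find(j)

    groups: dict[int, list[ResolvedElement]] = {}
    for i, e in enumerate(flow):
        groups.setdefault(find(i), []).append(e)

    out = []
    for members in groups.values():
        union = _close(shapely.unary_union([e.polygon for e in members]))
        out.append(FlowGroup(tuple(e.node_id for e in members), union))
    out.sort(key=lambda g: g.members)
    return out


def fitted_border(group: FlowGroup, border_width: float) -> sgeom.base.BaseGeometry:
    """Shape-fitting wax ring of constant *border_width* around a flow group.

    Returns ``(union ⊕ w) \\ union``: a closed ring that never crosses
    the hydrophilic union itself, so continuous channels stay open.
    """
    if border_width <= 0:
        raise GeometryError("border width must be > 0")
    union = group.footprint
    if union.is_empty or union.area == 0:
        raise GeometryError("degenerate flow union")
    return union.buffer(border_width, quad_segs=BUFFER_QUAD_SEGS).difference(union)


def full_field(elements: list[ResolvedElement], canvas: tuple[float, float, float, float]):
    """Canvas rectangle minus the union of flow footprints (white-on-black).

    *canvas* is ``(minx, miny, maxx, maxy)`` in mm; every flow footprint
    must lie inside it.
    """
    box = sgeom.box(*canvas)
    for e in elements:
        if e.role is Role.FLOW and not box.buffer(1e-9).contains(e.polygon):
            raise GeometryError(f"footprint of {e.node_id!r} lies outside the canvas")
    union = flow_union(elements)
    if union.is_empty:
        return box
    return box.difference(union)


@dataclass
class CutPath:
    """Closed rings tracing a cut piece: one outer boundary plus holes.

    Ring orientation follows the usual convention: outer boundary
    counter-clockwise, holes clockwise.
    """

    rings: list[tuple[tuple[tuple[float, float], ...], bool]]  # (coords, is_hole)
    stroke_width: float

    @property
    def length(self) -> float:
        return sum(sgeom.LinearRing(coords).length for coords, _ in self.rings)


def cut_outline(group: FlowGroup, stroke_width: float) -> list[CutPath]:
    """Trace the union boundary of a flow group as cut paths.

    One :class:`CutPath` per disjoint piece of the union; path length
    approximates the union perimeter (circles are polygonalized).
    """
    if stroke_width <= 0:
        raise GeometryError("stroke width must be > 0")
    union = group.footprint
    pieces = list(union.geoms) if union.geom_type == "MultiPolygon" else [union]
    paths = []
    for piece in pieces:
        piece = orient(piece, sign=1.0)  # CCW exterior, CW holes
        rings: list[tuple[tuple[tuple[float, float], ...], bool]] = [
            (tuple(piece.exterior.coords), False)
        ]
        for interior in piece.interiors:
            rings.append((tuple(interior.coords), True))
        paths.append(CutPath(rings, stroke_width))
    return paths


def layer_wax_region(
    elements: list[ResolvedElement],
    mode: str,
    canvas: tuple[float, float, float, float],
    border_width: float,
) -> sgeom.base.BaseGeometry:
    """Wax (black) region for one layer in either wax render mode.

    ``wax_full``: canvas minus the flow union. ``wax_buffered``: the
    union of each group's fitted border, clipped to the canvas; adjacent
    groups' rings merge by a final union. Both modes share the same flow
    union, so the white (hydrophilic) region is identical inside the
    buffered rings' outer envelope.
    """
    if mode == "wax_full":
        return full_field(elements, canvas)
    if mode == "wax_buffered":
        groups = connected_components(elements)
        if not groups:
            return sgeom.Polygon()
        rings = [fitted_border(g, border_width) for g in groups]
        return (shapely.unary_union(rings)
                .difference(flow_union(elements))
                .intersection(sgeom.box(*canvas)))
    raise GeometryError(f"not a wax mode: {mode!r}")
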