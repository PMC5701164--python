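"""Deliverable emission: raster masks, dimensioned PDF sheets, SVG, origami grids.

Wax masks are binary by construction: anti-aliasing is off, black
pixels mean wax, and the hydrophilic (flow) region is painted white
last so that decor (text) can never eat into a channel. Rasters use a
top-left origin (the y-up math flips to y-down only here, at emission).

PDF sheets embed physical page dimensions so that a print comes out at
exactly the designed size; each device layer gets one page, tiled
row-major with as many copies as the printable area allows. Origami
fold sheets are built by tiling reused layers into a grid of cells
under exact 90°-multiple rotations and axis reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import shapely
import shapely.affinity
import shapely.geometry as sgeom
from PIL import Image, ImageDraw, ImageFont

from .geometry import connected_components, cut_outline, flow_union, layer_wax_region
from .layout import ResolvedElement, resolve
from .model import MM_PER_INCH, DeviceDesign, RenderMode, Role, ShapeKind

__all__ = [
    "RenderError",
    "SheetLayout",
    "SheetSpec",
    "TileTransform",
    "combine_layers",
    "design_canvas",
    "export_cut_svg",
    "export_layers_svg",
    "render_layer",
    "tile_sheet",
    "write_pdf",
]

DEFAULT_DPI = 600


class RenderError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sheet & tile specifications

@dataclass
class SheetSpec:
    """Physical page for tiled output. All stored lengths are mm."""

    page_width: float = 8.5 * MM_PER_INCH
    page_height: float = 11.0 * MM_PER_INCH
    margin: float = 5.0
    spacing: float = 2.0
    dpi: int = DEFAULT_DPI
    order: str = "row_major"

    def __post_init__(self) -> None:
        if self.page_width <= 0 or self.page_height <= 0:
            raise RenderError("page dimensions must be positive")
        if self.margin < 0 or self.spacing < 0:
            raise RenderError("margins and spacing must be >= 0")

    @classmethod
    def letter(cls, **kwargs) -> "SheetSpec":
        return cls(8.5 * MM_PER_INCH, 11.0 * MM_PER_INCH, **kwargs)


_ROT = {0: (1.0, 0.0), 90: (0.0, 1.0), 180: (-1.0, 0.0), 270: (0.0, -1.0)}


@dataclass(frozen=True)
class TileTransform:
    """One grid cell of an origami fold sheet: a reused layer, transformed.

    Reflection (about the cell-local x or y axis) is applied before
    rotation; both are exact isometries, with rotation restricted to
    multiples of 90°.
    """

    row: int
    col: int
    source_layer: int
    rotation: int = 0          # degrees, in {0, 90, 180, 270}
    reflection: str = "none"   # none | x | y

    def __post_init__(self) -> None:
        if self.rotation % 360 not in _ROT:
            raise RenderError(f"rotation must be a multiple of 90°, got {self.rotation}")
        if self.reflection not in ("none", "x", "y"):
            raise RenderError(f"reflection must be none|x|y, got {self.reflection!r}")

    def apply(self, x: float, y: float) -> tuple[float, float]:
        """Map a cell-local point (origin at cell center) through the isometry."""
        if self.reflection == "x":
            y = -y
        elif self.reflection == "y":
            x = -x
        c, s = _ROT[self.rotation % 360]
        return (c * x - s * y, s * x + c * y)


# ---------------------------------------------------------------------------
# canvas & rasterization

def design_canvas(design: DeviceDesign, resolved: list[ResolvedElement] | None = None
                  ) -> tuple[float, float, float, float]:
    """Shared canvas rectangle (mm) for every layer of a design.

    The union bbox of all layers plus ``defaults.canvas_margin``, so
    stacked layers render onto congruent canvases and stay registered.
    """
    elements = resolved if resolved is not None else resolve(design)
    if not elements:
        m = design.defaults.canvas_margin
        return (-m, -m, m, m)
    minx = min(e.polygon.bounds[0] for e in elements)
    miny = min(e.polygon.bounds[1] for e in elements)
    maxx = max(e.polygon.bounds[2] for e in elements)
    maxy = max(e.polygon.bounds[3] for e in elements)
    m = design.defaults.canvas_margin
    return (minx - m, miny - m, maxx + m, maxy + m)


class _Raster:
    """mm -> pixel transform with the y-flip applied at emission."""

    def __init__(self, canvas: tuple[float, float, float, float], dpi: int):
        self.minx, self.miny, self.maxx, self.maxy = canvas
        self.scale = dpi / MM_PER_INCH
        self.width = max(1, math.ceil((self.maxx - self.minx) * self.scale))
        self.height = max(1, math.ceil((self.maxy - self.miny) * self.scale))

    def xy(self, x: float, y: float) -> tuple[float, float]:
        return ((x - self.minx) * self.scale, (self.maxy - y) * self.scale)

    def ring(self, coords) -> list[tuple[float, float]]:
        return [self.xy(x, y) for x, y in coords]


def _polygons(geom) -> list[sgeom.Polygon]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        out = []
        for g in geom.geoms:
            out.extend(_polygons(g))
        return out
    return []


def _draw_geom(draw: ImageDraw.ImageDraw, geom, raster: _Raster, ink: int, paper: int) -> None:
    # larger polygons first so islands inside holes are painted after their host
    for poly in sorted(_polygons(geom), key=lambda p: p.area, reverse=True):
        draw.polygon(raster.ring(poly.exterior.coords), fill=ink)
        for interior in poly.interiors:
            draw.polygon(raster.ring(interior.coords), fill=paper)


def _load_font(px: int, name: str | None = None) -> ImageFont.ImageFont:
    if name:
        try:
            return ImageFont.truetype(name, px)
        except OSError:
            pass
    try:
        return ImageFont.load_default(size=px)  # Pillow's bundled scalable font
    except TypeError:  # very old Pillow: bitmap fallback
        return ImageFont.load_default()


def _draw_text(image: Image.Image, element: ResolvedElement, design: DeviceDesign,
               raster: _Raster, ink: int) -> None:
    shape = design.node(element.node_id).shape if _has_node(design, element.node_id) else None
    if shape is None or shape.kind is not ShapeKind.TEXT:
        return
    from ._expr import eval_expression

    px = max(2, round(eval_expression(shape.height, design.parameters) * raster.scale))
    font = _load_font(px, shape.font)
    rotation = shape.rotation + element.orientation
    pad = 4 * px
    tile = Image.new("L", (2 * pad, 2 * pad), 255)
    ImageDraw.Draw(tile).text((pad, pad), shape.text, fill=0, font=font, anchor="mm")
    if rotation % 360:
        tile = tile.rotate(rotation, resample=Image.NEAREST, fillcolor=255)
    cx, cy = raster.xy(*element.center)
    glyph_mask = tile.point(lambda v: 255 if v < 128 else 0)
    solid = Image.new("L", tile.size, ink)
    image.paste(solid, (round(cx) - pad, round(cy) - pad), glyph_mask)


def _has_node(design: DeviceDesign, node_id: str) -> bool:
    try:
        design.node(node_id)
        return True
    except KeyError:
        return False


def render_layer(
    design: DeviceDesign,
    layer_index: int,
    mode: RenderMode | str | None = None,
    dpi: int = DEFAULT_DPI,
    resolved: list[ResolvedElement] | None = None,
) -> Image.Image:
    """Rasterize one layer as a binary mask (grayscale, no anti-aliasing).

    Wax modes paint the wax region black on white stock and repaint the
    flow union white last; cut mode strokes the outline paths only.
    Pixel dimensions are the physical canvas extent times dpi, rounded
    up, so doubling dpi doubles the raster within one pixel.
    """
    if dpi <= 0:
        raise RenderError("dpi must be positive")
    spec = design.layer(layer_index)  # KeyError for unknown layer
    mode = RenderMode(mode) if mode is not None else spec.render_mode
    elements = resolved if resolved is not None else resolve(design)
    canvas = design_canvas(design, elements)
    layer_elements = [e for e in elements if e.layer == layer_index]
    raster = _Raster(canvas, dpi)
    image = Image.new("L", (raster.width, raster.height), 255)
    draw = ImageDraw.Draw(image)

    if mode is RenderMode.CUT:
        stroke = max(1, round(design.defaults.cut_stroke * raster.scale))
        for path in _cut_paths(design, layer_elements):
            for coords, _ in path.rings:
                draw.line(raster.ring(coords), fill=0, width=stroke, joint="curve")
        return image

    wax = layer_wax_region(layer_elements, mode.value, canvas, design.defaults.border_width)
    _draw_geom(draw, wax, raster, ink=0, paper=255)
    # labels knock out of a full wax field and print as wax on white stock;
    # the flow union is painted last so decor can never eat into a channel
    text_ink = 255 if mode is RenderMode.WAX_FULL else 0
    for element in layer_elements:
        if element.role is Role.DECOR:
            _draw_text(image, element, design, raster, ink=text_ink)
    _draw_geom(draw, flow_union(layer_elements), raster, ink=255, paper=0)
    return image


def _cut_paths(design: DeviceDesign, layer_elements: list[ResolvedElement]):
    """Outline paths for a cut-mode layer (flow and cut roles alike)."""
    from dataclasses import replace as _replace

    cuttable = [
        _replace(e, role=Role.FLOW) if e.role is Role.CUT else e
        for e in layer_elements
        if e.role in (Role.FLOW, Role.CUT)
    ]
    paths = []
    for group in connected_components(cuttable):
        paths.extend(cut_outline(group, design.defaults.cut_stroke))
    return paths


# ---------------------------------------------------------------------------
# page tiling

@dataclass
class PageLayout:
    layer_index: int
    n_rows: int
    n_cols: int
    tiles: list[tuple[int, int, float, float]]  # (row, col, x0, y0) mm, top-left origin


@dataclass
class SheetLayout:
    sheet: SheetSpec
    device_width: float
    device_height: float
    canvas: tuple[float, float, float, float]
    pages: list[PageLayout] = field(default_factory=list)

    @property
    def tiles_per_page(self) -> int:
        return self.pages[0].n_rows * self.pages[0].n_cols if self.pages else 0


def tile_sheet(design: DeviceDesign, sheet: SheetSpec | None = None) -> SheetLayout:
    """Row-major tiling of every layer across a physical page.

    ``n_cols = ⌊(W − 2·margin + spacing) / (w + spacing)⌋`` and rows
    analogously; leftover space stays at the right/bottom. Raises
    :class:`RenderError` if the device does not fit the printable area.
    """
    sheet = sheet or design.sheet or SheetSpec.letter()
    resolved = resolve(design)
    canvas = design_canvas(design, resolved)
    w = canvas[2] - canvas[0]
    h = canvas[3] - canvas[1]
    avail_w = sheet.page_width - 2 * sheet.margin
    avail_h = sheet.page_height - 2 * sheet.margin
    if w > avail_w + 1e-9 or h > avail_h + 1e-9:
        raise RenderError(
            f"device ({w:.1f} x {h:.1f} mm) larger than printable area "
            f"({avail_w:.1f} x {avail_h:.1f} mm)")
    n_cols = int(math.floor((avail_w + sheet.spacing) / (w + sheet.spacing) + 1e-9))
    n_rows = int(math.floor((avail_h + sheet.spacing) / (h + sheet.spacing) + 1e-9))
    layout = SheetLayout(sheet, w, h, canvas)
    for spec in design.layers:
        tiles = [
            (r, c, sheet.margin + c * (w + sheet.spacing), sheet.margin + r * (h + sheet.spacing))
            for r in range(n_rows)
            for c in range(n_cols)
        ]
        layout.pages.append(PageLayout(spec.index, n_rows, n_cols, tiles))
    return layout


def _geom_to_patch(geom, transform, facecolor):
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path

    vertices: list[tuple[float, float]] = []
    codes: list[int] = []
    for poly in _polygons(geom):
        for ring in [poly.exterior, *poly.interiors]:
            pts = [transform(x, y) for x, y in ring.coords]
            vertices.extend(pts)
            codes.extend([Path.MOVETO] + [Path.LINETO] * (len(pts) - 2) + [Path.CLOSEPOLY])
    if not vertices:
        return None
    return PathPatch(Path(vertices, codes), facecolor=facecolor, edgecolor="none", lw=0)


def write_pdf(design: DeviceDesign, path, sheet: SheetSpec | None = None) -> SheetLayout:
    """Emit the tiled, physically-dimensioned PDF: one page per layer.

    The PDF page MediaBox equals the sheet dimensions exactly, so a
    100 %-scale print reproduces the designed mm dimensions.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.backends.backend_pdf import PdfPages
    from matplotlib.figure import Figure

    layout = tile_sheet(design, sheet)
    sheet = layout.sheet
    resolved = resolve(design)
    canvas = layout.canvas
    with PdfPages(path) as pdf:
        for page in layout.pages:
            spec = design.layer(page.layer_index)
            layer_elements = [e for e in resolved if e.layer == page.layer_index]
            fig = Figure(figsize=(sheet.page_width / MM_PER_INCH, sheet.page_height / MM_PER_INCH))
            ax = fig.add_axes((0, 0, 1, 1))
            ax.set_xlim(0, sheet.page_width)
            ax.set_ylim(sheet.page_height, 0)  # y-down page coordinates
            ax.set_axis_off()
            for row, col, x0, y0 in page.tiles:
                def tf(x, y, x0=x0, y0=y0):
                    # design mm (y-up) -> page mm (y-down), tile origin at (x0, y0)
                    return (x0 + (x - canvas[0]), y0 + (canvas[3] - y))

                if spec.render_mode is RenderMode.CUT:
                    for cpath in _cut_paths(design, layer_elements):
                        for coords, _ in cpath.rings:
                            xs, ys = zip(*[tf(x, y) for x, y in coords])
                            ax.plot(xs, ys, color="black",
                                    lw=design.defaults.cut_stroke * 72 / MM_PER_INCH)
                else:
                    wax = layer_wax_region(layer_elements, spec.render_mode.value, canvas,
                                           design.defaults.border_width)
                    patch = _geom_to_patch(wax, tf, "black")
                    if patch is not None:
                        ax.add_patch(patch)
            pdf.savefig(fig)
    return layout


# ---------------------------------------------------------------------------
# origami: combined layers

def combine_layers(
    design: DeviceDesign,
    grid: list[TileTransform],
    cell_size: float | None = None,
) -> list[ResolvedElement]:
    """Tile (reused, transformed) layers into one synthetic fold-sheet layer.

    Every grid cell is a square of ``cell_size`` mm (default: the
    largest source-layer extent, so all cells are uniform). Each tile
    maps its source layer's elements by reflection-then-rotation about
    the layer's bbox center, then translates them into the cell;
    distances within a tile are preserved exactly. Cell rows grow
    downward from a top-left origin.
    """
    from dataclasses import replace as _replace

    resolved = resolve(design)
    by_layer: dict[int, list[ResolvedElement]] = {}
    for e in resolved:
        by_layer.setdefault(e.layer, []).append(e)

    extents: dict[int, tuple[float, float, float, float]] = {}
    for tile in grid:
        if tile.source_layer not in by_layer:
            raise RenderError(f"source layer {tile.source_layer} has no elements")
        if tile.source_layer not in extents:
            elems = by_layer[tile.source_layer]
            extents[tile.source_layer] = (
                min(e.polygon.bounds[0] for e in elems),
                min(e.polygon.bounds[1] for e in elems),
                max(e.polygon.bounds[2] for e in elems),
                max(e.polygon.bounds[3] for e in elems),
            )
    needed = max(
        max(b[2] - b[0], b[3] - b[1]) for b in extents.values()
    )
    if cell_size is None:
        cell_size = needed
    elif cell_size < needed - 1e-9:
        raise RenderError(f"grid cell {cell_size} mm smaller than source layer extent {needed:.3f} mm")

    out_layer = max((spec.index for spec in design.layers), default=0) + 1
    combined: list[ResolvedElement] = []
    for tile in grid:
        b = extents[tile.source_layer]
        lcx, lcy = (b[0] + b[2]) / 2, (b[1] + b[3]) / 2
        ccx = tile.col * cell_size + cell_size / 2
        ccy = -(tile.row * cell_size + cell_size / 2)

        def tf(x: float, y: float) -> tuple[float, float]:
            rx, ry = tile.apply(x - lcx, y - lcy)
            return (ccx + rx, ccy + ry)

        for e in by_layer[tile.source_layer]:
            poly = sgeom.Polygon(
                [tf(x, y) for x, y in e.polygon.exterior.coords],
                [[tf(x, y) for x, y in ring.coords] for ring in e.polygon.interiors],
            )
            combined.append(_replace(
                e,
                node_id=f"{e.node_id}@r{tile.row}c{tile.col}",
                parent_id=None,
                layer=out_layer,
                center=tf(*e.center),
                polygon=poly,
                cross_layer=False,
            ))
    return combined


# ---------------------------------------------------------------------------
# SVG export

def _svg_ring(coords, maxy: float) -> str:
    return "M " + " L ".join(f"{x:.4f},{maxy - y:.4f}" for x, y in coords) + " Z"


def export_cut_svg(paths, canvas: tuple[float, float, float, float]) -> str:
    """Stroke-only SVG (mm units) of cut paths, for plotter/laser import."""
    minx, miny, maxx, maxy = canvas
    w, h = maxx - minx, maxy - miny
    body = []
    for path in paths:
        d = " ".join(_svg_ring([(x - minx, y - miny) for x, y in coords], h)
                     for coords, _ in path.rings)
        body.append(
            f'  <path d="{d}" fill="none" stroke="black" stroke-width="{path.stroke_width}"/>'
        )
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}mm" height="{h}mm" '
        f'viewBox="0 0 {w} {h}">\n' + "\n".join(body) + "\n</svg>\n"
    )


def export_layers_svg(design: DeviceDesign, resolved: list[ResolvedElement] | None = None) -> str:
    """Layered SVG of resolved footprints: one group per layer (mm units)."""
    elements = resolved if resolved is not None else resolve(design)
    minx, miny, maxx, maxy = design_canvas(design, elements)
    w, h = maxx - minx, maxy - miny
    groups: dict[int, list[str]] = {}
    for e in elements:
        d = _svg_ring([(x - minx, y - miny) for x, y in e.polygon.exterior.coords], h)
        fill = {"flow": "#9ecae1", "cut": "none", "decor": "#cccccc"}[e.role.value]
        stroke = "black" if e.role is Role.CUT else "none"
        groups.setdefault(e.layer, []).append(
            f'    <path d="{d}" fill="{fill}" stroke="{stroke}" stroke-width="0.2">'
            f"<title>{e.node_id}</title></path>"
        )
    body = []
    for layer in sorted(groups):
        body.append(f'  <g id="layer{layer}">')
        body.extend(groups[layer])
        body.append("  </g>")
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}mm" height="{h}mm" '
        f'viewBox="0 0 {w} {h}">\n' + "\n".join(body) + "\n</svg>\n"
    )
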