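"""Emission: binary masks, dpi law, page tiling, origami grids, PDF metadata."""

import math
import re

import numpy as np
import pytest

from padcad.fixtures import make_case_study, origami_fold_grid
from padcad.layout import resolve
from padcad.model import (
    Defaults,
    DesignNode,
    DeviceDesign,
    LayerSpec,
    Material,
    RenderMode,
    Shape,
)
from padcad.render import (
    RenderError,
    SheetSpec,
    TileTransform,
    combine_layers,
    render_layer,
    tile_sheet,
    write_pdf,
)


def _square_device(side_mm: float) -> DeviceDesign:
    design = DeviceDesign(
        layers=[LayerSpec(1, Material.PAPER)], defaults=Defaults(canvas_margin=0.0))
    design.roots.append(DesignNode("sq", Shape.rect(side_mm, side_mm)))
    return design


# --- rasters ----------------------------------------------------------------

def test_doubling_dpi_doubles_pixel_dimensions():
    design = make_case_study("splitter1L")
    lo = render_layer(design, 1, dpi=150)
    hi = render_layer(design, 1, dpi=300)
    assert abs(hi.width - 2 * lo.width) <= 2
    assert abs(hi.height - 2 * lo.height) <= 2


def test_masks_are_binary():
    design = make_case_study("splitter1L")
    image = render_layer(design, 1, RenderMode.WAX_BUFFERED, dpi=200)
    values = set(np.unique(np.asarray(image)))
    assert values <= {0, 255}


def test_wax_modes_have_identical_white_pixels_inside_envelope():
    """No hydrophilic pixel is ever waxed: white pixels of the full field
    are white in the buffered mask too, and inside the buffered ring's
    outer envelope (eroded by two pixels to dodge boundary rounding) the
    two white sets coincide exactly."""
    from padcad.geometry import flow_union
    from padcad.model import MM_PER_INCH
    from padcad.render import _Raster, _draw_geom, design_canvas
    from PIL import Image, ImageDraw

    design = make_case_study("splitter1L")
    resolved = resolve(design)
    dpi = 300
    full = np.asarray(render_layer(design, 1, RenderMode.WAX_FULL, dpi=dpi, resolved=resolved))
    buffered = np.asarray(
        render_layer(design, 1, RenderMode.WAX_BUFFERED, dpi=dpi, resolved=resolved))
    white_full, white_buf = full == 255, buffered == 255
    assert not np.any(white_full & ~white_buf)  # buffered never waxes flow

    canvas = design_canvas(design, resolved)
    raster = _Raster(canvas, dpi)
    env_geom = flow_union(resolved).buffer(1.5).buffer(-2 * MM_PER_INCH / dpi)
    env_img = Image.new("L", (raster.width, raster.height), 0)
    _draw_geom(ImageDraw.Draw(env_img), env_geom, raster, ink=255, paper=0)
    env = np.asarray(env_img) == 255
    assert np.array_equal(white_full & env, white_buf & env)


def _circle_with_label(with_label: bool):
    from padcad.model import Placement

    design = DeviceDesign(layers=[LayerSpec(1, Material.PAPER)])
    a = DesignNode("a", Shape.circle(6.0))
    a.children.append(DesignNode("b", Shape.circle(6.0), Placement(0.0, 30.0)))
    if with_label:
        a.children.append(DesignNode("lab", Shape.label("AB", 3.0), Placement(0.0, 15.0)))
    design.roots.append(a)
    return design


def test_toggling_text_changes_no_flow_pixels():
    """Labels are decor: adding one renders visibly but never alters the
    hydrophilic (flow) pixel set."""
    with_text = np.asarray(render_layer(_circle_with_label(True), 1,
                                        RenderMode.WAX_FULL, dpi=300))
    without = np.asarray(render_layer(_circle_with_label(False), 1,
                                      RenderMode.WAX_FULL, dpi=300))
    assert with_text.shape == without.shape
    assert np.any(with_text != without)                 # the label did render
    assert not np.any((without == 255) & (with_text == 0))  # flow whites intact
    # flow pixels: white set of the label-free full field
    diff = (with_text == 255) & (without == 0)          # label knockout pixels only
    ys, xs = np.nonzero(diff)
    assert ys.size > 0


def test_unknown_layer_raises():
    with pytest.raises(KeyError):
        render_layer(make_case_study("splitter1L"), 9)


def test_cut_mode_renders_stroke_paths_only():
    design = make_case_study("twoDPN")
    image = np.asarray(render_layer(design, 1, dpi=200))
    black = (image == 0).mean()
    assert 0 < black < 0.1  # outlines, not filled regions


# --- page tiling ------------------------------------------------------------

def test_letter_page_tiles_88_one_inch_devices():
    layout = tile_sheet(
        _square_device(25.4), SheetSpec(8.5 * 25.4, 11 * 25.4, margin=0.0, spacing=0.0))
    assert (layout.pages[0].n_cols, layout.pages[0].n_rows) == (8, 11)
    assert layout.tiles_per_page == 88


def test_page_sized_device_tiles_once():
    layout = tile_sheet(_square_device(100.0), SheetSpec(100.0, 100.0, margin=0.0, spacing=0.0))
    assert layout.tiles_per_page == 1


def test_oversized_device_rejected():
    with pytest.raises(RenderError, match="larger than printable"):
        tile_sheet(_square_device(120.0), SheetSpec(100.0, 100.0, margin=0.0, spacing=0.0))


def test_tile_count_matches_floor_arithmetic_oracle():
    import random

    rng = random.Random(42)
    for _ in range(25):
        w = rng.uniform(10, 60)
        margin = rng.uniform(0, 10)
        spacing = rng.uniform(0, 5)
        page_w = rng.uniform(w + 2 * margin, 300)
        page_h = rng.uniform(w + 2 * margin, 300)
        layout = tile_sheet(_square_device(w), SheetSpec(page_w, page_h, margin, spacing))
        expect_cols = math.floor((page_w - 2 * margin + spacing) / (w + spacing) + 1e-9)
        expect_rows = math.floor((page_h - 2 * margin + spacing) / (w + spacing) + 1e-9)
        assert (layout.pages[0].n_cols, layout.pages[0].n_rows) == (expect_cols, expect_rows)


def test_tiles_stay_inside_printable_area():
    layout = tile_sheet(_square_device(23.0), SheetSpec(210.0, 297.0, margin=7.0, spacing=3.0))
    sheet = layout.sheet
    for page in layout.pages:
        for _, _, x0, y0 in page.tiles:
            assert x0 >= sheet.margin - 1e-9
            assert y0 >= sheet.margin - 1e-9
            assert x0 + layout.device_width <= sheet.page_width - sheet.margin + 1e-9
            assert y0 + layout.device_height <= sheet.page_height - sheet.margin + 1e-9


def test_pdf_page_dimensions_match_sheet(tmp_path):
    design = make_case_study("splitter1L")
    sheet = SheetSpec(8.5 * 25.4, 11 * 25.4)
    write_pdf(design, tmp_path / "out.pdf", sheet)
    data = (tmp_path / "out.pdf").read_bytes()
    boxes = re.findall(rb"MediaBox\s*\[\s*([0-9.]+) ([0-9.]+) ([0-9.]+) ([0-9.]+)\s*\]", data)
    assert boxes, "no MediaBox found"
    for x0, y0, x1, y1 in boxes:
        assert float(x1) == pytest.approx(8.5 * 72, abs=0.5)
        assert float(y1) == pytest.approx(11 * 72, abs=0.5)


# --- origami combined layers ------------------------------------------------

def _pairwise_distances(elements):
    pts = [e.center for e in elements]
    return [math.dist(p, q) for i, p in enumerate(pts) for q in pts[i + 1:]]


def test_identity_tile_is_congruent_to_source():
    design = make_case_study("origami")
    source = [e for e in resolve(design) if e.layer == 1]
    combined = combine_layers(design, [TileTransform(0, 0, source_layer=1)])
    assert len(combined) == len(source)
    for a, b in zip(_pairwise_distances(source), _pairwise_distances(combined)):
        assert b == pytest.approx(a, abs=1e-9)


def test_rotating_twice_by_90_equals_180():
    import shapely.affinity

    design = make_case_study("origami")
    cell = 20.0
    a = combine_layers(design, [TileTransform(0, 0, source_layer=1, rotation=180)], cell_size=cell)
    b = combine_layers(design, [TileTransform(0, 0, source_layer=1, rotation=90)], cell_size=cell)
    center = (cell / 2, -cell / 2)
    for ea, eb in zip(a, b):
        rotated = shapely.affinity.rotate(eb.polygon, 90, origin=center)
        assert rotated.symmetric_difference(ea.polygon).area == pytest.approx(0.0, abs=1e-9)


def test_fold_grid_reuses_three_unique_layers():
    grid = origami_fold_grid()
    assert len(grid) == 9
    assert {t.source_layer for t in grid} == {1, 2, 3}
    first_row = [t for t in grid if t.row == 0]
    assert all(t.rotation == 0 and t.reflection == "none" for t in first_row)
    assert any(t.rotation != 0 for t in grid if t.row > 0)


def test_all_tile_transforms_are_isometric():
    design = make_case_study("origami")
    per_layer = {}
    for e in resolve(design):
        per_layer.setdefault(e.layer, []).append(e)
    combined = combine_layers(design, origami_fold_grid())
    by_tile = {}
    for e in combined:
        tag = e.node_id.split("@")[1]
        by_tile.setdefault(tag, []).append(e)
    for tile in origami_fold_grid():
        tag = f"r{tile.row}c{tile.col}"
        src = _pairwise_distances(per_layer[tile.source_layer])
        dst = _pairwise_distances(by_tile[tag])
        for a, b in zip(src, dst):
            assert b == pytest.approx(a, abs=1e-9)


def test_cell_smaller_than_layer_extent_rejected():
    design = make_case_study("origami")
    with pytest.raises(RenderError, match="smaller than source layer extent"):
        combine_layers(design, [TileTransform(0, 0, source_layer=1)], cell_size=5.0)
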