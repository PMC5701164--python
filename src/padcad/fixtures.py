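"""Programmatic generators for six reference device designs.

These reconstruct, at the topology level, classic µPAD architectures
from the literature: a single-layer 1-to-3 sample splitter, a 96-zone
paper microzone plate with text labels, a cut two-dimensional paper
network (2DPN), a stacked 3-D immunoassay (paper/nylon + adhesive), a
3-D sample splitter that fans 4 samples out to 64 test zones, and an
origami fold sheet built from three reused layers. Absolute feature
dimensions (zone diameters, channel widths) are not part of any
reference claim; defaults are common wax-printing practice (3 mm zones,
1 mm channels) and every knob is overridable. Everything a reference
count depends on — element counts, layer structure, refactoring
propagation — is pure topology.

All generators are deterministic: the same configuration serializes to
the byte-identical script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    Attach,
    DesignNode,
    DeviceDesign,
    LayerSpec,
    Material,
    Placement,
    RenderMode,
    Role,
    Shape,
    ShapeKind,
)

__all__ = [
    "FIXTURE_NAMES",
    "SplitterConfig",
    "first_stage_channels",
    "make_case_study",
    "make_figure2_device",
    "origami_fold_grid",
]

FIXTURE_NAMES = ("splitter1L", "microzone96", "twoDPN", "immunoassay3D", "splitter3D", "origami")


def _node(node_id, shape, angle=0.0, dist=0.0, attach=Attach.CENTER, layer=1):
    return DesignNode(node_id, shape, Placement(angle, dist, attach), layer=layer)


# ---------------------------------------------------------------------------
# single-layer 1-to-3 splitter

def _splitter1l(arm_length: float = 6.0, zone_diameter: float = 5.0) -> DeviceDesign:
    design = DeviceDesign(
        name="splitter1L",
        parameters={"arm": float(arm_length)},
        layers=[LayerSpec(1, Material.PAPER, RenderMode.WAX_BUFFERED)],
    )
    center = _node("center", Shape.circle(4.0))
    for k, angle in enumerate((90.0, 210.0, 330.0)):
        channel = _node(f"ch{k}", Shape.rect("arm", 1.2), angle=angle, attach=Attach.ABUT)
        channel.add(_node(f"zone{k}", Shape.circle(zone_diameter), angle=angle, attach=Attach.ABUT))
        center.add(channel)
    design.roots.append(center)
    return design


# ---------------------------------------------------------------------------
# 96-zone paper microzone plate

def _microzone(rows: int = 8, cols: int = 12, pitch: float = 9.0,
               zone_diameter: float = 6.0, label_height: float = 3.0) -> DeviceDesign:
    design = DeviceDesign(
        name="microzone96",
        layers=[LayerSpec(1, Material.PAPER, RenderMode.WAX_FULL)],
    )
    prev_row_head: DesignNode | None = None
    for r in range(rows):
        row_letter = chr(ord("A") + r)
        head = _node(f"{row_letter}1", Shape.circle(zone_diameter),
                     angle=270.0, dist=0.0 if r == 0 else pitch)
        head.add(_node(f"lab_{row_letter}", Shape.label(row_letter, label_height),
                       angle=180.0, dist=pitch))
        prev = head
        for c in range(1, cols):
            prev = prev.add(_node(f"{row_letter}{c + 1}", Shape.circle(zone_diameter),
                                  angle=0.0, dist=pitch))
        if r == 0:  # column labels sit above row A, one per zone in the chain
            col = 0
            zone = head
            while True:
                col += 1
                zone.add(_node(f"lab_{col}", Shape.label(str(col), label_height),
                               angle=90.0, dist=pitch))
                nxt = [c for c in zone.children if c.shape.kind is ShapeKind.CIRCLE]
                if not nxt:
                    break
                zone = nxt[0]
        if prev_row_head is None:
            design.roots.append(head)
        else:
            prev_row_head.add(head)
        prev_row_head = head
    return design


# ---------------------------------------------------------------------------
# two-dimensional paper network (cut layer)

def _twodpn(arm_length: float = 12.0, stem_length: float = 14.0) -> DeviceDesign:
    design = DeviceDesign(
        name="twoDPN",
        parameters={"arm": float(arm_length), "stem": float(stem_length)},
        layers=[LayerSpec(1, Material.MEMBRANE, RenderMode.CUT)],
    )
    junction = _node("junction", Shape.polygon([(-3.0, -2.0), (3.0, -2.0), (2.0, 2.5), (-2.0, 2.5)]))
    for k, angle in enumerate((60.0, 120.0)):
        channel = _node(f"arm{k}", Shape.rect("arm", 3.0), angle=angle, attach=Attach.ABUT)
        channel.add(_node(f"inlet{k}", Shape.circle(6.0), angle=angle, attach=Attach.ABUT))
        junction.add(channel)
    stem = _node("stem", Shape.rect("stem", 3.0), angle=270.0, attach=Attach.ABUT)
    stem.add(_node("sink", Shape.circle(8.0), angle=270.0, attach=Attach.ABUT))
    junction.add(stem)
    design.roots.append(junction)
    # a separate wicking pad: its own cut piece
    design.roots.append(_node("pad", Shape.rect(12.0, 8.0), angle=270.0, dist=40.0))
    return design


# ---------------------------------------------------------------------------
# stacked 3-D immunoassay (5 patterned + 5 adhesive layers)

def _immunoassay(lateral_length: float = 10.0) -> DeviceDesign:
    layers = []
    for i in range(1, 10):
        if i % 2 == 0:
            layers.append(LayerSpec(i, Material.ADHESIVE, RenderMode.CUT))
        else:
            material = Material.MEMBRANE if i == 7 else Material.PAPER
            layers.append(LayerSpec(i, material, RenderMode.WAX_BUFFERED))
    layers.append(LayerSpec(10, Material.ADHESIVE, RenderMode.CUT))
    design = DeviceDesign(
        name="immunoassay3D",
        parameters={"lat": float(lateral_length)},
        layers=layers,
    )
    sample = _node("sample", Shape.circle(5.0), layer=1)
    parent = sample
    for layer in (3, 5, 7, 9):
        parent = parent.add(_node(f"z{layer}", Shape.circle(5.0), layer=layer))
    lateral = _node("lateral", Shape.rect("lat", 2.0), angle=0.0,
                    attach=Attach.ABUT, layer=5)
    lateral.add(_node("lat_out", Shape.circle(4.0), angle=0.0, attach=Attach.ABUT, layer=5))
    sample.children[0].children[0].add(lateral)  # hangs off z5
    # bottom affixing adhesive, patterned explicitly
    parent.add(_node("seal", Shape.circle(3.0), layer=10))
    design.roots.append(sample)
    return design


# ---------------------------------------------------------------------------
# 3-D sample splitter (4 samples -> 64 test zones)

@dataclass
class SplitterConfig:
    """Knobs for the 3-D splitter; the defaults are the reference device."""

    samples: int = 4
    stages: tuple[int, ...] = (2, 2, 4)   # fan-out per split stage
    channel_length: float = 6.0           # mm, parameter "seg"
    channel_width: float = 1.0
    zone_diameter: float = 3.0
    pitch: float = 40.0                   # sample-to-sample spacing, mm

    def __post_init__(self) -> None:
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if any(f not in (2, 3, 4) for f in self.stages):
            raise ValueError("each fan-out must be 2, 3 or 4")


def _stage_angles(stage: int, fan: int) -> list[float]:
    if fan == 4:
        start = 45.0
    elif fan == 2:
        start = 90.0 if stage % 2 == 0 else 0.0
    else:
        start = 90.0 if stage % 2 == 0 else 30.0
    return [(start + k * 360.0 / fan) % 360.0 for k in range(fan)]


def _splitter3d(config: SplitterConfig | None = None, **overrides) -> DeviceDesign:
    config = config or SplitterConfig(**overrides)
    n_stages = len(config.stages)
    layers = []
    for i in range(1, 2 * n_stages + 4):  # inlet + per-stage (adhesive, paper) + final pair
        if i % 2 == 0:
            layers.append(LayerSpec(i, Material.ADHESIVE, RenderMode.CUT))
        else:
            layers.append(LayerSpec(i, Material.PAPER, RenderMode.WAX_BUFFERED))
    design = DeviceDesign(
        name="splitter3D",
        parameters={"seg": float(config.channel_length)},
        layers=layers,
    )

    def build_unit(zone: DesignNode, stage: int) -> None:
        """Attach one split unit's channels/outlets below *zone*, recursing."""
        paper_layer = zone.layer
        for k, angle in enumerate(_stage_angles(stage, config.stages[stage])):
            channel = _node(f"{zone.id}.c{k}", Shape.rect("seg", config.channel_width),
                            angle=angle, attach=Attach.ABUT, layer=paper_layer)
            outlet = channel.add(_node(f"{zone.id}.o{k}", Shape.circle(config.zone_diameter),
                                       angle=angle, attach=Attach.ABUT, layer=paper_layer))
            below = outlet.add(_node(f"{zone.id}.o{k}.z", Shape.circle(config.zone_diameter),
                                     layer=paper_layer + 2))
            if stage + 1 < n_stages:
                build_unit(below, stage + 1)
            zone.add(channel)

    for s in range(config.samples):
        inlet = _node(f"s{s}", Shape.circle(config.zone_diameter),
                      angle=0.0, dist=s * config.pitch, layer=1)
        unit_zone = inlet.add(_node(f"s{s}.z", Shape.circle(config.zone_diameter), layer=3))
        build_unit(unit_zone, 0)
        design.roots.append(inlet)
    return design


def first_stage_channels(design: DeviceDesign) -> list[str]:
    """Ids of the rectangular channels on the second paper layer (layer 3)."""
    return [n.id for n in design.nodes()
            if n.layer == 3 and n.shape.kind is ShapeKind.RECT]


# ---------------------------------------------------------------------------
# origami fold sheet from three reused layers

def _origami() -> DeviceDesign:
    design = DeviceDesign(
        name="origami",
        layers=[LayerSpec(i, Material.PAPER, RenderMode.WAX_BUFFERED) for i in (1, 2, 3)],
    )
    hub = _node("hub", Shape.circle(4.0), layer=1)
    for k, angle in enumerate((0.0, 90.0, 180.0, 270.0)):
        hub.add(_node(f"hub.c{k}", Shape.rect(5.0, 1.5), angle=angle,
                      attach=Attach.ABUT, layer=1))
    design.roots.append(hub)

    elbow = _node("elbow", Shape.circle(4.0), layer=2)
    for k, angle in enumerate((0.0, 90.0)):
        ch = elbow.add(_node(f"elbow.c{k}", Shape.rect(6.0, 1.5), angle=angle,
                             attach=Attach.ABUT, layer=2))
        if k == 0:
            ch.add(_node("elbow.z", Shape.circle(3.0), angle=angle, attach=Attach.ABUT, layer=2))
    design.roots.append(elbow)

    spoke = _node("spoke", Shape.circle(4.0), layer=3)
    ch = spoke.add(_node("spoke.c", Shape.rect(6.0, 1.5), angle=90.0,
                         attach=Attach.ABUT, layer=3))
    ch.add(_node("spoke.z", Shape.circle(3.0), angle=90.0, attach=Attach.ABUT, layer=3))
    design.roots.append(spoke)
    return design


def origami_fold_grid():
    """Default 3×3 fold grid: row 0 holds the three unique layers, later
    rows reuse them under rotation (one cell also exercises reflection)."""
    from .render import TileTransform

    return [
        TileTransform(0, 0, source_layer=1),
        TileTransform(0, 1, source_layer=2),
        TileTransform(0, 2, source_layer=3),
        TileTransform(1, 0, source_layer=2, rotation=180),
        TileTransform(1, 1, source_layer=3, rotation=90),
        TileTransform(1, 2, source_layer=1, rotation=180),
        TileTransform(2, 0, source_layer=3, rotation=270),
        TileTransform(2, 1, source_layer=1, rotation=90),
        TileTransform(2, 2, source_layer=2, rotation=90, reflection="x"),
    ]


# ---------------------------------------------------------------------------
# miniature three-layer refactoring demo (1 sample -> 6 outputs)

def make_figure2_device(L: float = 10.0) -> DeviceDesign:
    """Three-layer demo: a central zone feeds three zones at distance L;
    each zone feeds a splitting channel on layer 2 and two test zones on
    layer 3 — six terminal outputs. Moving one zone's distance from
    ``L`` to ``2*L`` repositions exactly that zone's branch."""
    if L <= 3.5:
        raise ValueError("L must exceed 3.5 mm (zone radii leave no channel)")
    design = DeviceDesign(
        name="figure2",
        parameters={"L": float(L)},
        layers=[LayerSpec(i, Material.PAPER, RenderMode.WAX_BUFFERED) for i in (1, 2, 3)],
    )
    center = _node("center", Shape.circle(4.0), layer=1)
    for k, angle in enumerate((90.0, 210.0, 330.0)):
        zone = center.add(_node(f"zone{k}", Shape.circle(3.0), angle=angle, dist="L", layer=1))
        back = zone.add(_node(f"link{k}", Shape.rect("L-3.5", 1.0),
                              angle=(angle + 180.0) % 360.0, attach=Attach.ABUT, layer=1))
        split = zone.add(_node(f"split{k}", Shape.rect(12.0, 1.0),
                               angle=(angle + 90.0) % 360.0, layer=2))
        for j, a in enumerate(((angle + 90.0) % 360.0, (angle - 90.0) % 360.0)):
            end = split.add(_node(f"end{k}_{j}", Shape.circle(3.0), angle=a,
                                  attach=Attach.ABUT, layer=2))
            end.add(_node(f"test{k}_{j}", Shape.circle(3.0), layer=3))
    design.roots.append(center)
    return design


# ---------------------------------------------------------------------------

_BUILDERS = {
    "splitter1L": _splitter1l,
    "microzone96": _microzone,
    "twoDPN": _twodpn,
    "immunoassay3D": _immunoassay,
    "splitter3D": _splitter3d,
    "origami": _origami,
}


def make_case_study(which: str, **overrides) -> DeviceDesign:
    """Build one of the six reference designs; overrides reach the
    builder's declared knobs only. Raises ``ValueError`` for an unknown
    fixture id."""
    try:
        builder = _BUILDERS[which]
    except KeyError:
        raise ValueError(f"unknown fixture {which!r}; choose from {FIXTURE_NAMES}") from None
    return builder(**overrides)
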