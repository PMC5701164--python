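"""Shared fixtures: small hand-built designs and a random-tree generator."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from padcad.model import (
    Attach,
    DesignNode,
    DeviceDesign,
    LayerSpec,
    Material,
    Placement,
    RenderMode,
    Shape,
)

REPO_ROOT = Path(__file__).resolve().parents[1]
EXAMPLES = REPO_ROOT / "examples"


@pytest.fixture
def one_circle() -> DeviceDesign:
    design = DeviceDesign(name="one", layers=[LayerSpec(1, Material.PAPER)])
    design.roots.append(DesignNode("c", Shape.circle(5.0)))
    return design


def random_tree_design(rng: random.Random, n_nodes: int = 8) -> DeviceDesign:
    """A random small design over a paper/adhesive/paper stack.

    Nodes attach to a uniformly chosen existing node, staying on the
    same layer, stepping to an adjacent layer, or hopping layer 1 -> 3
    across the adhesive (which exercises auto-generated holes).
    """
    design = DeviceDesign(
        name="rand",
        layers=[
            LayerSpec(1, Material.PAPER),
            LayerSpec(2, Material.ADHESIVE, RenderMode.CUT),
            LayerSpec(3, Material.PAPER),
        ],
    )
    root = DesignNode("n0", Shape.circle(rng.uniform(2, 6)), layer=1)
    design.roots.append(root)
    nodes = [root]
    for i in range(1, n_nodes):
        parent = rng.choice(nodes)
        cross = parent.layer == 1 and rng.random() < 0.3
        layer = 3 if cross else parent.layer
        if rng.random() < 0.5:
            shape = Shape.circle(rng.uniform(2, 6))
        else:
            shape = Shape.rect(rng.uniform(3, 10), rng.uniform(0.5, 2))
        placement = Placement(
            angle=rng.choice([0, 45, 90, 135, 180, 225, 270, 315]) + rng.uniform(-10, 10),
            distance=0.0 if cross else rng.uniform(1, 15),
            attach=Attach.CENTER if cross or rng.random() < 0.5 else Attach.ABUT,
        )
        node = DesignNode(f"n{i}", shape, placement, layer=layer)
        parent.children.append(node)
        nodes.append(node)
    return design


def proper_descendants(design: DeviceDesign, node_id: str) -> set[str]:
    """Brute-force subtree traversal oracle (independent of the layout engine)."""
    node = design.node(node_id)
    out: set[str] = set()
    stack = list(node.children)
    while stack:
        n = stack.pop()
        out.add(n.id)
        stack.extend(n.children)
    return out


def expected_moved_ids(design: DeviceDesign, edited_id: str) -> set[str]:
    """Oracle for a position-changing single-node edit: the edited node,
    its proper descendants, and the auto-generated adhesive hole of every
    moved flow connection that hops two layers."""
    moved = {edited_id} | proper_descendants(design, edited_id)
    parents = design.parents()
    for nid in list(moved):
        node = design.node(nid)
        parent_id = parents[nid]
        if parent_id is not None:
            parent = design.node(parent_id)
            if abs(node.layer - parent.layer) == 2:
                moved.add(f"{nid}@adh{(node.layer + parent.layer) // 2}")
    return moved
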