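# padcad

Scriptable CAD for paper-based microfluidic devices (µPADs): write a
short text script describing a device as a tree of connected shapes,
and compile it into wax-print masks, cut outlines for knife plotters
and laser cutters, and physically-dimensioned, page-tiled PDF print
sheets. It is aimed at labs that prototype paper diagnostics and today
redraw every design iteration by hand in general-purpose vector
software.

## The idea: relative layout, automatic refactoring

A design is a forest of nodes. Every node carries a shape with physical
dimensions (mm) and a *relative* placement — an angle θ and a distance
d to its parent, where d may be an arithmetic expression over named
parameters (`dist=2*L`). Absolute coordinates exist only after layout:

- `attach=center`: child center = parent center + d·(cos θ, sin θ)
- `attach=abut`: the child's near boundary touches the parent boundary
  along θ (a channel of length ℓ abutting a circle of diameter D spans
  the rim to D/2 + ℓ)
- a cross-layer child at d = 0 is centered exactly on its parent, which
  keeps stacked layers registered for reproducible capillary flow

Because placement is relative, editing one parameter or one node and
re-resolving repositions exactly the edited nodes and their descendants
— across all layers — and nothing else. Flow connections that hop an
adhesive layer get circular through-holes auto-inserted on it. Masks
come in two wax modes: `wax_full` (white channels on a black field) and
`wax_buffered` (a constant-width, shape-fitting border around each
connected hydrophilic group, which uses less wax); `cut` layers are
traced as closed outline rings.

## Worked example

Six reference designs are bundled (`padcad fixtures all --out DIR`,
also committed under `examples/`). The four-sample three-dimensional
sample splitter fans each inlet through 1→2, 1→2, 1→4 split stages down
a nine-layer paper/adhesive stack:

```console
$ padcad compile examples/splitter3D.apad --out out --dpi 150
design   splitter3D
layers   9
counts   L1:4 L2:4 L3:20 L4:8 L5:40 L6:16 L7:144 L8:64 L9:64
total    364
pages    9
tiles    6 per page (6x1)
```

364 elements: 4 inlets, then per stage a paper layer of split units
(inlet zone + channels + outlet zones) and an adhesive layer of
auto-generated holes, ending in 64 test zones. The output directory
holds one PNG mask per layer, stroke-only SVG cut paths for the
adhesive layers, and a letter-size PDF whose pages are dimensionally
exact (6 device copies tiled per page).

Lengthen one first-stage channel and diff the two scripts:

```console
$ padcad diff examples/splitter3D.apad edited.apad
{
  "moved": 44,
  "by_material": { "adhesive": 11, "paper": 33 },
  ...
}
```

44 moved elements are the edited channel itself plus 43 downstream
elements dragged along with it — 32 on paper layers and 11 adhesive
holes. Editing all 8 first-stage channels moves 8 × 43 = 344 elements.
That is the point of the tool: one number changed in the script, and
every dependent zone, channel, and through-hole on seven downstream
layers lands re-aligned.

From Python the same takes a few lines:

```python
from padcad import make_case_study, resolve, refactor, diff_positions
from padcad.fixtures import first_stage_channels

design = make_case_study("splitter3D")
ch = first_stage_channels(design)[0]
edited = refactor(design, node_edits={ch: {"length": 9.0}})
diff = diff_positions(resolve(design), resolve(edited))
print(len(diff.moved - {ch}), diff.by_material)   # 43 {'paper': 33, 'adhesive': 11}
```

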