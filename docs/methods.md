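# Methods

## The design model

A device is a forest of *nodes*. Each node owns a shape — circle,
rectangle, simple polygon, or text — with physical dimensions in
millimetres, and a *relative placement*: an angle θ (degrees,
counter-clockwise, 0° along +x, y up), a distance (a number or an
arithmetic expression over named parameters), and an attachment mode.
Nothing in a design stores absolute coordinates; the layout engine
derives them, which is what makes edits propagate: changing one
parameter or one node's property and re-resolving repositions exactly
the edited nodes and their descendants, across every layer of the
stack, while all other elements resolve bit-identically.

Placement semantics:

- `attach=center` — child center sits at parent center + d·(cos θ, sin θ).
- `attach=abut` — the child's near boundary touches the parent boundary
  along θ; the distance adds an extra gap. Half-extents are computed
  from exact support functions (circle d/2; rectangle by its oriented
  half-dimensions; polygon by the vertex support maximum), so a channel
  of length ℓ abutting a circle of diameter d spans from the rim to
  d/2 + ℓ from the parent center. Rectangles (and text boxes) orient
  lengthwise along their placement angle.
- A cross-layer child at distance 0 is centered exactly on its parent —
  the alignment guarantee stacked devices need for reproducible
  capillary flow. `check_alignment` verifies every cross-layer pair
  (footprint overlap and center offset ≤ tolerance); on all bundled
  designs the residual is exactly 0.

Layer 1 is the top of the stack. Expressions are evaluated at resolve
time, not parse time, so parameter edits re-layout a parsed design
without re-parsing. Children resolve in declaration order and node ids
are stable under refactoring, so position diffs are well defined.

## Adhesive through-holes

A flow connection that hops two layers across a declared adhesive layer
gets a circular hole auto-inserted on that layer at the child's
placement (the child re-attaches to the hole at distance 0, leaving all
positions unchanged). The hole diameter is `min(parent flow width,
child flow width)` — a circle's width is its diameter, a channel's its
short side — unless `defaults.hole_diameter` overrides it. Insertion is
a normalisation pass re-run inside every resolve/count, with ids
derived from the child id (`<child>@adh<N>`), so hole diameters track
parameter edits and diffs across refactorings are well defined.
Auto-holes count as elements; they are exactly the adhesive-layer
objects in the splitter tallies below.

## The splitter arithmetic

The four-sample 3-D splitter fans each inlet through a 1→2, 1→2, 1→4
split cascade. With s samples the per-layer object counts are
(s, s, 5s, 2s, 10s, 4s, 36s, 16s, 16s) — each binary split unit is
1 inlet zone + 2 channels + 2 outlet zones, each 1→4 unit is 9 objects,
and every cross-layer hop contributes one adhesive hole. s = 4 gives
(4, 4, 20, 8, 40, 16, 144, 64, 64), 364 in total. Lengthening one
first-stage channel (second paper layer, stack layer 3) translates its
whole subtree rigidly: 43 further elements move — 32 on paper layers
(1 outlet + 5 + 18 + 8 test zones) and 11 on adhesive layers
(1 + 2 + 8 holes). Editing all 8 such channels moves 8 × 43 = 344.
Moved counts exclude the edited channels themselves (an abut-attached
channel's own center shifts by half the length change, so a raw diff
reports 44 and 352; the propagation counts are the interesting
quantity). `scripts/acceptance.py` recomputes all four numbers from
scratch; the edit magnitude and which channel is edited are drawn from
the seed precisely because the counts are invariant to both.

## Geometry

Polygon set operations go through shapely. Circles are polygonalized at
128 chords (module constant); offsets use 32 arc segments per quadrant.
Exact-rim abutment of two polygonalized circles can leave a chord-depth
gap of order 10⁻⁴ mm, so connectivity uses a 10⁻³ mm tolerance and the
per-layer flow union applies a morphological closing at that radius —
the boundary perturbation is sub-pixel at any practical dpi. Both wax
render modes subtract this same union, which makes the hydrophilic
(white) region identical between them by construction:

- `wax_full` — canvas minus the flow union (white channels on black).
- `wax_buffered` — per connected component, the constant-width ring
  `(U ⊕ w) \ U` ("snap-to-shape"); adjacent rings merge by a final
  union. Ring area is always ≤ the full field's wax area (the
  less-wax property, asserted per layer in the tests).

Area and length assertions on polygonalized arcs carry a 0.5 %
tolerance. Cut layers trace the union boundary of each connected piece
as closed rings, exterior counter-clockwise and holes clockwise, and
export as stroke-only SVG (mm units) for knife plotters and laser
cutters. Default border width 1.5 mm and cut stroke 0.2 mm are common
wax-printing / plotter practice and are per-design overridable.

## Emission

Masks are rasterized with anti-aliasing off so pixel-set assertions are
exact: wax is painted black, text labels are drawn next (knocked out
white on a full field, inked black in buffered mode), and the flow
union is painted white last — decor can therefore never eat into a
channel. Rasters use a top-left origin; the y-flip happens only here.
Text metrics come from Pillow's bundled scalable font (a named font
file can be given per label); decor never participates in connectivity
or buffering, so label metrics do not affect any fluidic geometry.

PDF sheets (matplotlib's vector backend) embed one page per layer with
the page MediaBox equal to the requested sheet size, so 100 %-scale
prints are dimensionally exact. Tiling is row-major from the top-left:
`n_cols = ⌊(W − 2·margin + spacing)/(w + spacing)⌋`, rows analogously,
leftover space at the right/bottom. All layers share one canvas (design
bbox + 2 mm margin by default), so tiles of different layers land
congruently and stacked prints register.

Origami fold sheets reuse layer designs across a grid of uniform square
cells; each tile applies reflection (about the cell-local x or y axis)
then rotation (exact 90° multiples, via an integer cos/sin table) about
the source layer's bbox center. Transforms are isometries to 10⁻⁹ mm.

## The bundled reference designs

Six generators cover the pipeline end to end: a single-layer 1→3
splitter (one 7-member connected group; exercises snap-to-shape
buffering), a 96-zone microzone plate with row/column text labels on a
9 mm pitch, a cut-mode two-dimensional paper network plus a separate
wicking pad (two cut pieces), a 10-layer stacked immunoassay (5
paper/nylon + 5 adhesive; four adhesives auto-generated by traversal,
the bottom affixing film declared explicitly), the four-sample 3-D
splitter above, and a 3-layer origami device whose 3×3 fold grid reuses
the three unique layers under rotation. A miniature three-layer demo
device (central zone, three zones at parameterised distance L, six
terminal outputs) exercises single-zone L → 2·L refactoring.

Absolute feature dimensions (3 mm zones, 1 mm channels, 40 mm sample
pitch…) are package choices within common wax-printing practice — every
reference quantity reproduced here is a count or a topological
property, never a length. Fixtures are deterministic (a configuration
serializes byte-identically) and each also ships as a committed `.apad`
script under `examples/` used as parser golden files.

What the generators do not emulate: wax melt spreading (barrier widths
are nominal pre-melt patterns), capillary flow, fold feasibility of
origami arrangements, and the exact dimensions of the photographed
literature devices. Passing tests therefore establish the CAD
arithmetic — layout, propagation, masks, tiling — not assay behaviour
on paper.

## Numerical choices and limitations

- Diff tolerance 10⁻⁶ mm: layout is closed-form, so genuine motion
  exceeds float noise by many orders of magnitude.
- Expression language is deliberately tiny (+, −, ×, ÷, parentheses);
  no functions, so a hole diameter rule needing `min` is computed at
  normalisation time rather than stored as an expression.
- Text footprints are nominal boxes (0.6 × height advance per glyph);
  adequate for decor, not for typesetting.
- No constraint solving beyond tree propagation: simultaneous
  constraints (e.g. "these two leaves must coincide") are out of scope.
- One page per layer in the PDF; mixed-layer pages are not emitted.
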