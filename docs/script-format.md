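# The `.apad` script format

Device scripts are plain UTF-8 text, one statement per line. `#`
starts a comment; blank lines are ignored; the decimal separator is
always `.`. A script is a header (name, parameters, layers, defaults,
optional sheet block) followed by node lines.

```
# a one-layer splitter
device demo
param L = 10                     # named parameter, usable in expressions
layer 1 paper wax_buffered       # index, material, render mode
default border=1.5 cut_stroke=0.2 margin=2
sheet page=8.5x11in margin=5 spacing=2 dpi=600

> id=inlet shape=circle d=4 layer=1
>> id=ch shape=rect len=2*L w=1 angle=240 attach=abut layer=1
>>> id=zone shape=circle d=5 angle=240 attach=abut layer=1
```

## Header directives

| directive | form | notes |
|---|---|---|
| `device` | `device NAME` | design name |
| `param` | `param NAME = VALUE` | VALUE may reference earlier parameters |
| `layer` | `layer N MATERIAL [MODE]` | material: `paper`, `adhesive`, `membrane`; mode: `wax_full`, `wax_buffered`, `cut` (alias `$CUT`); indices must be contiguous from 1 (1 = top) |
| `default` | `default border= cut_stroke= margin= [hole_d=]` | mm |
| `sheet` | `sheet page=WxH{in,mm} margin= spacing= dpi=` | page for tiled PDF output |

## Node lines

A node line starts with `>` repeated to the node's depth; a node at
depth d+1 is a child of the nearest preceding node at depth d. The
rest of the line is `key=value` properties separated by whitespace
(values must not contain spaces; text strings are double-quoted with
`\"` and `\\` escapes). A bare `$CUT` token sets the node's role to
`cut`.

| key | meaning |
|---|---|
| `id` | unique token (auto-assigned if omitted) |
| `shape` | `circle`, `rect`, `polygon`, `text` |
| `d` | circle diameter, mm or expression |
| `len`, `w` | rect length (along the placement angle) and width |
| `points` | polygon vertices `x,y;x,y;...`, mm offsets about the anchor |
| `text`, `h`, `rot`, `font` | label string, cap height, rotation, font name |
| `role` | `flow` (default), `cut`, `decor` (default for text) |
| `angle` | placement angle, degrees CCW from +x |
| `dist` | placement distance, mm or expression (default 0) |
| `attach` | `center` (default) or `abut` |
| `layer` | layer index (default: the parent's; required on roots) |

Lengths and distances accept arithmetic expressions over declared
parameters (`+ - * /` and parentheses, e.g. `dist=2*L`); they are
evaluated at layout time, so editing a `param` re-lays-out the design.

A cross-layer child may target the adjacent layer, or hop two layers
when the layer between is adhesive — the interpreter then auto-inserts
a through-hole on the adhesive layer (see `docs/methods.md`).

`padcad fixtures all --out DIR` writes the six bundled reference
designs as scripts; the same files are committed under `examples/`.
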