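"""Plain-text script format (``.apad``) for device designs.

The script is line-oriented. Header lines declare the device name,
named parameters, layers and optional defaults/sheet block; body lines
declare nodes, one per line, with ``>`` repeated to the node's depth —
a node at depth d+1 becomes a child of the nearest preceding node at
depth d. ``#`` starts a comment. Encoding is UTF-8 and the decimal
point is always ``.`` regardless of locale.

Example::

    device splitter
    param L = 10
    layer 1 paper wax_buffered
    > id=inlet shape=circle d=3 layer=1
    >> id=ch shape=rect len=2*L w=1 angle=240 attach=abut layer=1

``$CUT`` is accepted both as a layer render mode and as a bare node
token (mapping the node's role to ``cut``). The full grammar is
documented in ``docs/script-format.md``.
"""

from __future__ import annotations

import re

from ._expr import ExpressionError, eval_expression  # re-exported: part of this module's surface
from .model import (
    MM_PER_INCH,
    Attach,
    Defaults,
    DesignNode,
    DeviceDesign,
    LayerSpec,
    Material,
    Placement,
    RenderMode,
    Role,
    Shape,
    ShapeKind,
    validate,
)

__all__ = ["ScriptError", "parse_script", "serialize_script", "eval_expression", "ExpressionError"]

SCRIPT_EXTENSION = ".apad"


class ScriptError(ValueError):
    """Script syntax or semantic error, carrying a 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# parsing

def _split_tokens(body: str, line_no: int) -> list[str]:
    """Split on whitespace but keep double-quoted spans (with \\ escapes) intact."""
    tokens: list[str] = []
    buf: list[str] = []
    in_quote = False
    escape = False
    for ch in body:
        if in_quote:
            buf.append(ch)
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_quote = False
        elif ch == '"':
            buf.append(ch)
            in_quote = True
        elif ch.isspace():
            if buf:
                tokens.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if in_quote:
        raise ScriptError(line_no, "unterminated string")
    if buf:
        tokens.append("".join(buf))
    return tokens


def _unquote(value: str, line_no: int) -> str:
    if not (value.startswith('"') and value.endswith('"') and len(value) >= 2):
        raise ScriptError(line_no, f"expected quoted string, got {value}")
    out: list[str] = []
    escape = False
    for ch in value[1:-1]:
        if escape:
            out.append(ch)
            escape = False
        elif ch == "\\":
            escape = True
        else:
            out.append(ch)
    return "".join(out)


def _quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _num_or_expr(value: str) -> float | str:
    try:
        return float(value)
    except ValueError:
        return value


def _parse_float(value: str, line_no: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ScriptError(line_no, f"{what} must be a number, got {value!r}") from None


_PAGE_RE = re.compile(r"^(?P<w>[0-9.]+)x(?P<h>[0-9.]+)(?P<unit>in|mm)$")


def _parse_sheet(tokens: list[str], line_no: int):
    from .render import SheetSpec

    kwargs = {}
    for tok in tokens:
        if "=" not in tok:
            raise ScriptError(line_no, f"bad sheet property {tok!r}")
        key, value = tok.split("=", 1)
        if key == "page":
            m = _PAGE_RE.match(value)
            if m is None:
                raise ScriptError(line_no, f"bad page size {value!r} (use WxHin or WxHmm)")
            scale = MM_PER_INCH if m.group("unit") == "in" else 1.0
            kwargs["page_width"] = float(m.group("w")) * scale
            kwargs["page_height"] = float(m.group("h")) * scale
        elif key == "margin":
            kwargs["margin"] = _parse_float(value, line_no, "margin")
        elif key == "spacing":
            kwargs["spacing"] = _parse_float(value, line_no, "spacing")
        elif key == "dpi":
            kwargs["dpi"] = int(_parse_float(value, line_no, "dpi"))
        else:
            raise ScriptError(line_no, f"unknown sheet property {key!r}")
    return SheetSpec(**kwargs)


_SHAPE_KEYS = {"d", "len", "w", "points", "text", "h", "rot", "font", "role"}


def _parse_node(depth: int, tokens: list[str], line_no: int, auto_ids: list[int]) -> DesignNode:
    props: dict[str, str] = {}
    role: Role | None = None
    for tok in tokens:
        if tok == "$CUT":
            role = Role.CUT
            continue
        if "=" not in tok:
            raise ScriptError(line_no, f"bad property {tok!r} (expected key=value)")
        key, value = tok.split("=", 1)
        props[key] = value

    kind_name = props.get("shape")
    if kind_name is None:
        raise ScriptError(line_no, "node needs shape=circle|rect|polygon|text")
    try:
        kind = ShapeKind(kind_name)
    except ValueError:
        raise ScriptError(line_no, f"unknown shape {kind_name!r}") from None

    if "role" in props:
        try:
            role = Role(props["role"])
        except ValueError:
            raise ScriptError(line_no, f"unknown role {props['role']!r}") from None
    if role is None:
        role = Role.DECOR if kind is ShapeKind.TEXT else Role.FLOW

    shape = Shape(kind, role=role)
    if kind is ShapeKind.CIRCLE:
        if "d" not in props:
            raise ScriptError(line_no, "circle needs d=<diameter>")
        shape.diameter = _num_or_expr(props["d"])
    elif kind is ShapeKind.RECT:
        if "len" not in props or "w" not in props:
            raise ScriptError(line_no, "rect needs len= and w=")
        shape.length = _num_or_expr(props["len"])
        shape.width = _num_or_expr(props["w"])
    elif kind is ShapeKind.POLYGON:
        if "points" not in props:
            raise ScriptError(line_no, "polygon needs points=x,y;x,y;...")
        verts = []
        for pair in props["points"].split(";"):
            xy = pair.split(",")
            if len(xy) != 2:
                raise ScriptError(line_no, f"bad vertex {pair!r}")
            verts.append((_parse_float(xy[0], line_no, "vertex x"),
                          _parse_float(xy[1], line_no, "vertex y")))
        shape.vertices = tuple(verts)
    elif kind is ShapeKind.TEXT:
        if "text" not in props:
            raise ScriptError(line_no, "text needs text=\"...\"")
        shape.text = _unquote(props["text"], line_no)
        shape.height = _num_or_expr(props.get("h", "3"))
        shape.rotation = _parse_float(props.get("rot", "0"), line_no, "rot")
        shape.font = props.get("font")

    placement = Placement(
        angle=_parse_float(props.get("angle", "0"), line_no, "angle"),
        distance=_num_or_expr(props.get("dist", "0")),
        attach=Attach(props["attach"]) if "attach" in props else Attach.CENTER,
    )

    node_id = props.get("id")
    if node_id is None:
        auto_ids[0] += 1
        node_id = f"n{auto_ids[0]}"
    layer = int(_parse_float(props["layer"], line_no, "layer")) if "layer" in props else -1
    return DesignNode(node_id, shape, placement, layer=layer, source_line=line_no)


def parse_script(text: str) -> DeviceDesign:
    """Parse an ``.apad`` script into a validated :class:`DeviceDesign`.

    Raises :class:`ScriptError` (with line number) on syntax errors,
    undeclared parameters or invariant violations.
    """
    design = DeviceDesign()
    stack: list[DesignNode] = []  # stack[d] = last node at depth d
    auto_ids = [0]

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue

        if line.lstrip().startswith(">"):
            stripped = line.lstrip()
            depth = len(stripped) - len(stripped.lstrip(">"))
            body = stripped[depth:]
            if depth - 1 > len(stack):
                raise ScriptError(line_no, f"node at depth {depth} has no depth-{depth - 1} ancestor")
            node = _parse_node(depth, _split_tokens(body, line_no), line_no, auto_ids)
            del stack[depth - 1:]
            if depth == 1:
                if node.layer == -1:
                    raise ScriptError(line_no, "root nodes must declare layer=")
                design.roots.append(node)
            else:
                parent = stack[depth - 2]
                if node.layer == -1:
                    node.layer = parent.layer
                parent.children.append(node)
            stack.append(node)
            continue

        tokens = _split_tokens(line.strip(), line_no)
        keyword = tokens[0]
        if keyword == "device":
            if len(tokens) != 2:
                raise ScriptError(line_no, "usage: device NAME")
            design.name = tokens[1]
        elif keyword == "param":
            # "param L = 10" — value may reference earlier parameters
            rest = "".join(tokens[1:])
            if "=" not in rest:
                raise ScriptError(line_no, "usage: param NAME = VALUE")
            name, value = rest.split("=", 1)
            try:
                design.parameters[name] = eval_expression(value, design.parameters)
            except ExpressionError as exc:
                raise ScriptError(line_no, str(exc)) from None
        elif keyword == "layer":
            if len(tokens) not in (3, 4):
                raise ScriptError(line_no, "usage: layer INDEX MATERIAL [MODE]")
            index = int(_parse_float(tokens[1], line_no, "layer index"))
            try:
                material = Material(tokens[2])
            except ValueError:
                raise ScriptError(line_no, f"unknown material {tokens[2]!r}") from None
            mode = RenderMode.WAX_BUFFERED
            if len(tokens) == 4:
                tok = tokens[3]
                if tok == "$CUT":
                    mode = RenderMode.CUT
                else:
                    try:
                        mode = RenderMode(tok)
                    except ValueError:
                        raise ScriptError(line_no, f"unknown render mode {tok!r}") from None
            design.layers.append(LayerSpec(index, material, mode))
        elif keyword == "default":
            for tok in tokens[1:]:
                if "=" not in tok:
                    raise ScriptError(line_no, f"bad default {tok!r}")
                key, value = tok.split("=", 1)
                num = _parse_float(value, line_no, key)
                if key == "border":
                    design.defaults.border_width = num
                elif key == "cut_stroke":
                    design.defaults.cut_stroke = num
                elif key == "margin":
                    design.defaults.canvas_margin = num
                elif key == "hole_d":
                    design.defaults.hole_diameter = num
                else:
                    raise ScriptError(line_no, f"unknown default {key!r}")
        elif keyword == "sheet":
            design.sheet = _parse_sheet(tokens[1:], line_no)
        else:
            raise ScriptError(line_no, f"unknown directive {keyword!r}")

    violations = validate(design)
    if violations:
        first = violations[0]
        where = ""
        try:
            where = f" (line {design.node(first.subject).source_line})"
        except KeyError:
            pass
        raise ScriptError(0, f"invalid design: [{first.code}] {first.subject}: {first.message}{where}"
                             + (f" (+{len(violations) - 1} more)" if len(violations) > 1 else ""))
    return design


# ---------------------------------------------------------------------------
# serialization

def _fmt_num(value: float) -> str:
    if float(value).is_integer() and abs(value) < 1e15:
        return str(int(value))
    return repr(float(value))


def _fmt_expr(value: float | str) -> str:
    if isinstance(value, str):
        return value.replace(" ", "")
    return _fmt_num(value)


def _node_line(node: DesignNode, depth: int) -> str:
    parts = [">" * depth, f"id={node.id}", f"shape={node.shape.kind.value}"]
    s = node.shape
    if s.kind is ShapeKind.CIRCLE:
        parts.append(f"d={_fmt_expr(s.diameter)}")
    elif s.kind is ShapeKind.RECT:
        parts.append(f"len={_fmt_expr(s.length)}")
        parts.append(f"w={_fmt_expr(s.width)}")
    elif s.kind is ShapeKind.POLYGON:
        parts.append("points=" + ";".join(f"{x!r},{y!r}" for x, y in s.vertices))
    elif s.kind is ShapeKind.TEXT:
        parts.append(f"text={_quote(s.text)}")
        parts.append(f"h={_fmt_expr(s.height)}")
        if s.rotation:
            parts.append(f"rot={_fmt_num(s.rotation)}")
        if s.font:
            parts.append(f"font={s.font}")
    default_role = Role.DECOR if s.kind is ShapeKind.TEXT else Role.FLOW
    if s.role is not default_role:
        parts.append(f"role={s.role.value}")
    p = node.placement
    if p.angle:
        parts.append(f"angle={_fmt_num(p.angle)}")
    if not (isinstance(p.distance, float) and p.distance == 0.0):
        parts.append(f"dist={_fmt_expr(p.distance)}")
    if p.attach is not Attach.CENTER:
        parts.append(f"attach={p.attach.value}")
    parts.append(f"layer={node.layer}")
    return " ".join(parts)


def serialize_script(design: DeviceDesign) -> str:
    """Serialize a validated design; ``parse_script`` round-trips it exactly."""
    lines = [f"device {design.name}"]
    for name, value in design.parameters.items():
        lines.append(f"param {name} = {_fmt_num(value)}")
    for spec in design.layers:
        lines.append(f"layer {spec.index} {spec.material.value} {spec.render_mode.value}")
    d = design.defaults
    default_line = f"default border={_fmt_num(d.border_width)} cut_stroke={_fmt_num(d.cut_stroke)} margin={_fmt_num(d.canvas_margin)}"
    if d.hole_diameter is not None:
        default_line += f" hole_d={_fmt_num(d.hole_diameter)}"
    lines.append(default_line)
    if design.sheet is not None:
        s = design.sheet
        lines.append(
            f"sheet page={_fmt_num(s.page_width)}x{_fmt_num(s.page_height)}mm "
            f"margin={_fmt_num(s.margin)} spacing={_fmt_num(s.spacing)} dpi={s.dpi}"
        )

    def emit(node: DesignNode, depth: int) -> None:
        lines.append(_node_line(node, depth))
        for child in node.children:
            emit(child, depth + 1)

    for root in design.roots:
        emit(root, 1)
    return "\n".join(lines) + "\n"
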