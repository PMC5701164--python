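"""Arithmetic expression evaluator for script parameters.

Device scripts may give any length as an expression over declared
parameters (e.g. ``2*L`` for a zone moved to twice the layout length).
The language is deliberately tiny: ``+ - * /``, parentheses, decimal
literals and parameter tokens. Expressions are kept as strings on the
design and evaluated at layout time, so editing a parameter re-lays-out
the device without re-parsing the script.
"""

from __future__ import annotations

import math
import re

__all__ = ["ExpressionError", "eval_expression"]

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?|\.\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[-+*/()]))"
)


class ExpressionError(ValueError):
    """Raised for syntax errors, undeclared tokens, or non-finite results."""


def _tokenize(expr: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ExpressionError(f"bad character {expr[pos:].strip()[0]!r} in {expr!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            text = m.group(kind)
            if text is not None:
                tokens.append((kind, text))
                break
    return tokens


class _Parser:
    # expr   := term (('+'|'-') term)*
    # term   := unary (('*'|'/') unary)*
    # unary  := ('-'|'+')* atom
    # atom   := number | name | '(' expr ')'

    def __init__(self, tokens: list[tuple[str, str]], params: dict[str, float], src: str):
        self.tokens = tokens
        self.params = params
        self.src = src
        self.i = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ExpressionError(f"unexpected end of expression in {self.src!r}")
        self.i += 1
        return tok

    def expr(self) -> float:
        value = self.term()
        while (tok := self.peek()) is not None and tok[1] in "+-":
            self.take()
            rhs = self.term()
            value = value + rhs if tok[1] == "+" else value - rhs
        return value

    def term(self) -> float:
        value = self.unary()
        while (tok := self.peek()) is not None and tok[1] in "*/":
            self.take()
            rhs = self.unary()
            if tok[1] == "*":
                value *= rhs
            else:
                if rhs == 0:
                    raise ExpressionError(f"division by zero in {self.src!r}")
                value /= rhs
        return value

    def unary(self) -> float:
        sign = 1.0
        while (tok := self.peek()) is not None and tok[0] == "op" and tok[1] in "+-":
            self.take()
            if tok[1] == "-":
                sign = -sign
        return sign * self.atom()

    def atom(self) -> float:
        kind, text = self.take()
        if kind == "num":
            return float(text)
        if kind == "name":
            if text not in self.params:
                raise ExpressionError(f"undeclared parameter {text!r} in {self.src!r}")
            return float(self.params[text])
        if text == "(":
            value = self.expr()
            tok = self.peek()
            if tok is None or tok[1] != ")":
                raise ExpressionError(f"missing ')' in {self.src!r}")
            self.take()
            return value
        raise ExpressionError(f"unexpected {text!r} in {self.src!r}")


def eval_expression(expr: str | float | int, params: dict[str, float] | None = None) -> float:
    """Evaluate *expr* against declared *params*; plain numbers pass through.

    Raises :class:`ExpressionError` on syntax errors, undeclared tokens,
    division by zero, or a non-finite result.
    """
    if isinstance(expr, (int, float)):
        value = float(expr)
    else:
        tokens = _tokenize(expr)
        if not tokens:
            raise ExpressionError("empty expression")
        parser = _Parser(tokens, dict(params or {}), expr)
        value = parser.expr()
        if parser.peek() is not None:
            raise ExpressionError(f"trailing tokens in {expr!r}")
    if not math.isfinite(value):
        raise ExpressionError(f"non-finite result for {expr!r}")
    return value
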