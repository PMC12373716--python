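"""Safe arithmetic expression evaluator for user-supplied shape functions.

Accepts a restricted subset of Python expression syntax over the variables
``x`` (the sequence entry), ``n`` (leaf count) and ``ninner`` (inner vertex
count), a whitelist of math functions, and conditional expressions for
piecewise definitions such as ``"x if x <= 3 else x + 2"``.  Anything
outside the whitelist (attribute access, subscripts, arbitrary names,
lambdas, comprehensions) is rejected at parse time, so CLI users cannot
execute code through a function string.
"""

from __future__ import annotations

import ast
import math
import operator
from typing import Callable

__all__ = ["ExpressionError", "compile_expression"]


class ExpressionError(ValueError):
    """Raised for syntactically invalid or disallowed expressions."""


_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.FloorDiv: operator.floordiv,
    ast.Mod: operator.mod,
    ast.Pow: operator.pow,
}

_UNARYOPS = {ast.USub: operator.neg, ast.UAdd: operator.pos}

_CMPOPS = {
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
}

_FUNCTIONS: dict[str, Callable] = {
    "log": math.log,
    "log2": math.log2,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "exp": math.exp,
    "abs": abs,
    "min": min,
    "max": max,
    "floor": math.floor,
    "ceil": math.ceil,
    "comb": math.comb,
}

_CONSTANTS = {"pi": math.pi, "e": math.e}

_VARIABLES = ("x", "n", "ninner")


def _check(node: ast.AST, source: str) -> None:
    if isinstance(node, ast.Expression):
        _check(node.body, source)
    elif isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        _check(node.left, source)
        _check(node.right, source)
    elif isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
        _check(node.operand, source)
    elif isinstance(node, ast.IfExp):
        _check(node.test, source)
        _check(node.body, source)
        _check(node.orelse, source)
    elif isinstance(node, ast.BoolOp):
        for v in node.values:
            _check(v, source)
    elif isinstance(node, ast.Compare):
        if any(type(op) not in _CMPOPS for op in node.ops):
            raise ExpressionError(f"disallowed comparison in {source!r}")
        _check(node.left, source)
        for c in node.comparators:
            _check(c, source)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            raise ExpressionError(f"disallowed function call in {source!r}")
        if node.keywords:
            raise ExpressionError(f"keyword arguments not allowed in {source!r}")
        for a in node.args:
            _check(a, source)
    elif isinstance(node, ast.Name):
        if node.id not in _VARIABLES and node.id not in _CONSTANTS:
            raise ExpressionError(
                f"unknown name {node.id!r} in {source!r}; allowed: "
                f"{', '.join(_VARIABLES + tuple(_CONSTANTS))}"
            )
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"disallowed constant {node.value!r} in {source!r}")
    else:
        raise ExpressionError(
            f"disallowed syntax {type(node).__name__} at position "
            f"{getattr(node, 'col_offset', '?')} in {source!r}"
        )


def compile_expression(source: str) -> Callable[..., float]:
    """Compile an expression string into ``f(x, n=None, ninner=None)``."""
    try:
        parsed = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(
            f"invalid expression {source!r} at position {exc.offset}: {exc.msg}"
        ) from exc
    _check(parsed, source)
    code = compile(parsed, "<shape-function>", "eval")
    namespace = {**_FUNCTIONS, **_CONSTANTS, "__builtins__": {}}

    def fn(x, n=None, ninner=None):
        return eval(code, namespace, {"x": x, "n": n, "ninner": ninner})

    fn.__name__ = f"expr[{source}]"
    return fn
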