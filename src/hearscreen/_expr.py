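"""Tiny safe arithmetic evaluator for branch-probability expressions.

Topology files may express a branch probability as a parameter name or as an
arithmetic combination of parameter names (products for joint probabilities,
differences/ratios for derived conditional rates).  Only +, -, *, /, unary
minus, numeric literals, and parameter names are permitted.
"""

from __future__ import annotations

import ast
from typing import Mapping

__all__ = ["eval_expr"]

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
}


def eval_expr(expr: str, values: Mapping[str, float]) -> float:
    """Evaluate ``expr`` with names resolved from ``values``."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise ValueError(f"malformed expression {expr!r}: {e}") from None
    return _eval(tree.body, expr, values)


def _eval(node: ast.AST, expr: str, values: Mapping[str, float]) -> float:
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)) and not isinstance(node.value, bool):
            return float(node.value)
        raise ValueError(f"{expr!r}: literal {node.value!r} is not numeric")
    if isinstance(node, ast.Name):
        try:
            return float(values[node.id])
        except KeyError:
            raise KeyError(f"{expr!r}: unknown parameter {node.id!r}") from None
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        return _BINOPS[type(node.op)](
            _eval(node.left, expr, values), _eval(node.right, expr, values)
        )
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        v = _eval(node.operand, expr, values)
        return -v if isinstance(node.op, ast.USub) else v
    raise ValueError(f"{expr!r}: unsupported syntax {type(node).__name__}")
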