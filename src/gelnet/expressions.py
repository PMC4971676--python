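"""Attribute-expression micro-language shared by select/foreach and the DSL.

Expressions range over a single record's attribute values plus the builtin
``degree()`` (nodes only): comparisons, arithmetic, boolean connectives and
literals.  Precedence from loosest to tightest: ``or``, ``and``, ``not``,
comparison, ``+ -``, ``* /``, unary minus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .graph_model import GraphError
from .lexer import GelSyntaxError, Token, TokenStream, tokenize

__all__ = ["Expr", "parse_expression", "compile_expression", "EvalContext"]

_COMPARE = {"<", "<=", "==", "!=", ">=", ">"}
_KEYWORDS = {"and", "or", "not", "true", "false", "degree"}


@dataclass(frozen=True)
class Expr:
    """AST node: ('lit', v) ('attr', name) ('degree',) ('neg', e) ('not', e)
    ('bin', op, l, r) ('bool', op, l, r) ('cmp', op, l, r)."""

    op: str
    args: tuple

    def references(self) -> set[str]:
        """All attribute names this expression reads."""
        if self.op == "attr":
            return {self.args[0]}
        out: set[str] = set()
        for a in self.args:
            if isinstance(a, Expr):
                out |= a.references()
        return out

    def uses_degree(self) -> bool:
        if self.op == "degree":
            return True
        return any(a.uses_degree() for a in self.args if isinstance(a, Expr))


def _parse_or(ts: TokenStream) -> Expr:
    left = _parse_and(ts)
    while ts.at_ident("or"):
        ts.next()
        left = Expr("bool", ("or", left, _parse_and(ts)))
    return left


def _parse_and(ts: TokenStream) -> Expr:
    left = _parse_not(ts)
    while ts.at_ident("and"):
        ts.next()
        left = Expr("bool", ("and", left, _parse_not(ts)))
    return left


def _parse_not(ts: TokenStream) -> Expr:
    if ts.at_ident("not"):
        ts.next()
        return Expr("not", (_parse_not(ts),))
    return _parse_cmp(ts)


def _parse_cmp(ts: TokenStream) -> Expr:
    left = _parse_arith(ts)
    if ts.at_op(*_COMPARE):
        op = ts.next().value
        return Expr("cmp", (op, left, _parse_arith(ts)))
    return left


def _parse_arith(ts: TokenStream) -> Expr:
    left = _parse_term(ts)
    while ts.at_op("+", "-"):
        op = ts.next().value
        left = Expr("bin", (op, left, _parse_term(ts)))
    return left


def _parse_term(ts: TokenStream) -> Expr:
    left = _parse_factor(ts)
    while ts.at_op("*", "/"):
        op = ts.next().value
        left = Expr("bin", (op, left, _parse_factor(ts)))
    return left


def _parse_factor(ts: TokenStream) -> Expr:
    t = ts.peek()
    if ts.accept_op("-"):
        return Expr("neg", (_parse_factor(ts),))
    if ts.accept_op("("):
        e = _parse_or(ts)
        ts.expect_op(")")
        return e
    if t.kind in ("INT", "REAL", "STRING"):
        ts.next()
        return Expr("lit", (t.value,))
    if t.kind == "IDENT":
        if t.value == "true":
            ts.next()
            return Expr("lit", (True,))
        if t.value == "false":
            ts.next()
            return Expr("lit", (False,))
        if t.value == "degree":
            ts.next()
            ts.expect_op("(")
            ts.expect_op(")")
            return Expr("degree", ())
        if t.value in _KEYWORDS:
            raise GelSyntaxError(f"unexpected keyword {t.value!r}", t.line, t.col)
        ts.next()
        return Expr("attr", (t.value,))
    raise GelSyntaxError(f"expected expression, found {t}", t.line, t.col)


def parse_expression(ts: TokenStream) -> Expr:
    return _parse_or(ts)


def compile_expression(text: str) -> Expr:
    """Parse a standalone expression string."""
    ts = TokenStream(tokenize(text))
    e = parse_expression(ts)
    ts.expect_eof()
    return e


@dataclass
class EvalContext:
    values: Mapping[str, object]
    degree: Callable[[], int] | None = None


def evaluate(e: Expr, ctx: EvalContext):
    op = e.op
    if op == "lit":
        return e.args[0]
    if op == "attr":
        name = e.args[0]
        if name not in ctx.values:
            raise GraphError(f"unknown attribute {name!r} in expression")
        return ctx.values[name]
    if op == "degree":
        if ctx.degree is None:
            raise GraphError("degree() is only available for node expressions")
        return ctx.degree()
    if op == "neg":
        return -evaluate(e.args[0], ctx)
    if op == "not":
        return not evaluate(e.args[0], ctx)
    if op == "bool":
        kind, l, r = e.args
        lv = evaluate(l, ctx)
        if kind == "and":
            return bool(lv) and bool(evaluate(r, ctx))
        return bool(lv) or bool(evaluate(r, ctx))
    if op == "cmp":
        kind, l, r = e.args
        lv, rv = evaluate(l, ctx), evaluate(r, ctx)
        try:
            if kind == "<":
                return lv < rv
            if kind == "<=":
                return lv <= rv
            if kind == ">":
                return lv > rv
            if kind == ">=":
                return lv >= rv
        except TypeError:
            raise GraphError(f"cannot compare {lv!r} and {rv!r}") from None
        if kind == "==":
            return lv == rv
        return lv != rv
    if op == "bin":
        kind, l, r = e.args
        lv, rv = evaluate(l, ctx), evaluate(r, ctx)
        if isinstance(lv, str) != isinstance(rv, str):
            raise GraphError(f"cannot mix string and number: {lv!r} {kind} {rv!r}")
        if isinstance(lv, str) and kind != "+":
            raise GraphError(f"operator {kind!r} undefined for strings")
        if kind == "+":
            return lv + rv
        if kind == "-":
            return lv - rv
        if kind == "*":
            return lv * rv
        if rv == 0:
            raise GraphError("division by zero in expression")
        return lv / rv
    raise AssertionError(f"unknown expression node {op!r}")
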