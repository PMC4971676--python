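"""Select and foreach: attribute/topology filtering and per-record updates.

``select`` pulls a subgraph out of a graph.  Node selection uses
induced-subgraph semantics (a link survives only if both endpoints were
selected); link selection uses endpoint-closure semantics (the endpoints of
every selected link are kept).  Both readings are needed in practice: pulling
hub links into a sub-network must keep their endpoints, while selecting a
gene set must not leave dangling links.

``foreach`` maps new attribute values across nodes or links, or tallies
(count/sum/min/max) over them.  Update expressions are evaluated against a
snapshot of each record's pre-update values, so results never depend on
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expressions import EvalContext, Expr, compile_expression, evaluate
from .graph_model import Graph, GraphError

__all__ = [
    "Predicate",
    "select_links",
    "select_nodes",
    "foreach_update",
    "foreach_tally",
]


@dataclass(frozen=True)
class Predicate:
    """A boolean expression over node or link attributes (plus degree() for nodes)."""

    target: str  # "node" | "link"
    expression: Expr

    def __post_init__(self):
        if self.target not in ("node", "link"):
            raise GraphError(f"predicate target must be node or link, got {self.target!r}")
        if self.target == "link" and self.expression.uses_degree():
            raise GraphError("degree() is not defined for link predicates")

    @classmethod
    def parse(cls, target: str, text: str) -> "Predicate":
        return cls(target, compile_expression(text))


def _as_expr(e) -> Expr:
    return compile_expression(e) if isinstance(e, str) else e


def _check_refs(g: Graph, target: str, expr: Expr) -> None:
    attrs = (
        g.schema.node_type.attrs if target == "node" else g.schema.link_type.attrs
    )
    declared = {a.name for a in attrs}
    missing = expr.references() - declared
    if missing:
        raise GraphError(
            f"unknown {target} attribute(s) in expression: {sorted(missing)}"
        )


def _node_ctx(g: Graph, name: str) -> EvalContext:
    return EvalContext(g.nodes[name], degree=lambda n=name: g.degree(n))


def select_links(g: Graph, p: Predicate | str) -> Graph:
    """Links satisfying *p* plus both endpoints of each (endpoint closure)."""
    if isinstance(p, str):
        p = Predicate.parse("link", p)
    if p.target != "link":
        raise GraphError("select_links requires a link predicate")
    _check_refs(g, "link", p.expression)
    out = Graph(g.schema)
    for key, rec in g.links.items():
        if evaluate(p.expression, EvalContext(rec)):
            for end in key:
                if end not in out.nodes:
                    out.nodes[end] = dict(g.nodes[end])
                    out._adj[end] = set()
            out.links[key] = dict(rec)
            out._adj[key[0]].add(key)
            out._adj[key[1]].add(key)
    return out


def select_nodes(g: Graph, p: Predicate | str) -> Graph:
    """Nodes satisfying *p* and the induced links (both endpoints selected)."""
    if isinstance(p, str):
        p = Predicate.parse("node", p)
    if p.target != "node":
        raise GraphError("select_nodes requires a node predicate")
    _check_refs(g, "node", p.expression)
    out = Graph(g.schema)
    for name, rec in g.nodes.items():
        if evaluate(p.expression, _node_ctx(g, name)):
            out.nodes[name] = dict(rec)
            out._adj[name] = set()
    for key, rec in g.links.items():
        if key[0] in out.nodes and key[1] in out.nodes:
            out.links[key] = dict(rec)
            out._adj[key[0]].add(key)
            out._adj[key[1]].add(key)
    return out


def _iter_matching(g: Graph, target: str, p: Predicate | str | None):
    if isinstance(p, str):
        p = Predicate.parse(target, p)
    if p is not None:
        if p.target != target:
            raise GraphError(f"predicate targets {p.target}, expected {target}")
        _check_refs(g, target, p.expression)
    if target == "node":
        for name, rec in g.nodes.items():
            ctx = _node_ctx(g, name)
            if p is None or evaluate(p.expression, ctx):
                yield name, rec, ctx
    else:
        for key, rec in g.links.items():
            ctx = EvalContext(rec)
            if p is None or evaluate(p.expression, ctx):
                yield key, rec, ctx


def foreach_update(
    g: Graph,
    target: str,
    assignments: list[tuple[str, Expr | str]],
    p: Predicate | str | None = None,
) -> Graph:
    """Assign ``attr := expression`` on every matching record.

    All expressions see the record's pre-update values (snapshot semantics),
    so ``a := b, b := a`` swaps the two attributes.
    """
    if target not in ("node", "link"):
        raise GraphError(f"foreach target must be node or link, got {target!r}")
    attrs = g.schema.node_type.attrs if target == "node" else g.schema.link_type.attrs
    by_name = {a.name: a for a in attrs}
    compiled = []
    for name, e in assignments:
        spec = by_name.get(name)
        if spec is None:
            raise GraphError(f"unknown {target} attribute {name!r} in assignment")
        e = _as_expr(e)
        _check_refs(g, target, e)
        compiled.append((spec, e))
    out = g.copy()
    records = out.nodes if target == "node" else out.links
    for key, _, ctx in list(_iter_matching(g, target, p)):
        rec = records[key]
        new = {}
        for spec, e in compiled:
            v = evaluate(e, ctx)
            if spec.ptype == "string":
                if not isinstance(v, str):
                    raise GraphError(f"cannot assign {v!r} to string attribute {spec.name!r}")
            elif spec.ptype == "int":
                if isinstance(v, bool) or not isinstance(v, int):
                    raise GraphError(f"cannot assign {v!r} to int attribute {spec.name!r}")
            else:
                if isinstance(v, str) or isinstance(v, bool):
                    raise GraphError(f"cannot assign {v!r} to {spec.ptype} attribute {spec.name!r}")
                v = float(v)
            new[spec.name] = v
        rec.update(new)
    return out


def foreach_tally(
    g: Graph,
    target: str,
    reducers: list[tuple[str, Expr | str | None]],
    p: Predicate | str | None = None,
) -> list:
    """Reduce over matching records: ('count', None) | ('sum'|'min'|'max', expr).

    count/sum of an empty selection are 0; min/max of an empty selection are
    an error.
    """
    compiled = []
    for kind, e in reducers:
        if kind == "count":
            compiled.append((kind, None))
            continue
        if kind not in ("sum", "min", "max"):
            raise GraphError(f"unknown reducer {kind!r}")
        e = _as_expr(e)
        _check_refs(g, target, e)
        compiled.append((kind, e))
    rows = [ctx for _, _, ctx in _iter_matching(g, target, p)]
    out = []
    for kind, e in compiled:
        if kind == "count":
            out.append(len(rows))
        else:
            vals = [evaluate(e, ctx) for ctx in rows]
            if kind == "sum":
                out.append(sum(vals))
            elif not vals:
                raise GraphError(f"{kind} over an empty selection")
            else:
                out.append(min(vals) if kind == "min" else max(vals))
    return out
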