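"""The eight binary graph operators with attribute merging and promotion.

Dotted operators (``.+  .-  .&``) act on both the node and link sets;
non-dotted operators (``+  -  &``) keep the left operand's node set and act
on links only.  ``*`` joins two graphs with all cross links between their
node sets (excluding self-pairs); ``**`` additionally creates self-loops for
shared nodes.

Attribute conflicts are resolved with left precedence: where a record exists
in both operands, the left value wins — unless the left value equals its
declared default and the right operand declares a matching attribute, in
which case the right value is copied (the "default exception").  The result
always takes the LEFT operand's schema; right-operand records are coerced to
it by attribute promotion (matched by name and primitive type).  Combining
graphs while preserving the attributes of both requires assigning each into a
graph of a wider type first.

Operators never mutate their operands.
"""

from __future__ import annotations

from typing import Mapping

from .graph_model import (
    AttributeSpec,
    Graph,
    GraphError,
    GraphSchema,
    coerce_record,
)

__all__ = [
    "merge_records",
    "dotted_add",
    "nondotted_add",
    "dotted_sub",
    "nondotted_sub",
    "dotted_intersect",
    "nondotted_intersect",
    "join_star",
    "join_double_star",
    "coerce_graph",
    "OPERATORS",
]


class MergePolicy:
    """Left precedence with a per-attribute default exception.

    Materialized as a class only for documentation and testability; the rule
    set itself is fixed.
    """

    @staticmethod
    def resolve(left_value, default, right_declares: bool, right_value):
        if left_value == default and right_declares:
            return right_value
        return left_value


def merge_records(
    left: Mapping[str, object],
    right: Mapping[str, object],
    target_attrs: tuple[AttributeSpec, ...],
    right_attrs: tuple[AttributeSpec, ...],
) -> dict:
    """Merge two conflicting records under the left-precedence policy.

    *left* conforms to *target_attrs*; *right* (declared by *right_attrs*)
    is first coerced to the target type.  Per attribute the left value wins
    unless it equals the declared default and the right record declared a
    matching attribute.
    """
    coerced = coerce_record(right, right_attrs, target_attrs)
    declared_right = {a.name for a in right_attrs}
    out = {}
    for a in target_attrs:
        out[a.name] = MergePolicy.resolve(
            left[a.name], a.default, a.name in declared_right, coerced[a.name]
        )
    return out


def coerce_graph(g: Graph, schema: GraphSchema) -> Graph:
    """Rebuild *g* under *schema* (attribute promotion applied to every record)."""
    if g.directed != schema.directed:
        raise GraphError("cannot coerce between directed and undirected schemas")
    out = Graph(schema)
    na, ta = g.schema.node_type.attrs, schema.node_type.attrs
    for name, rec in g.nodes.items():
        r = coerce_record(rec, na, ta)
        r[schema.node_type.name_attr] = name
        out.nodes[name] = r
        out._adj[name] = set(g._adj[name])
    la, tla = g.schema.link_type.attrs, schema.link_type.attrs
    for key, rec in g.links.items():
        out.links[key] = coerce_record(rec, la, tla)
    return out


def _check_operands(a: Graph, b: Graph) -> None:
    if a.directed != b.directed:
        raise GraphError("cannot combine a directed and an undirected graph")


def _fresh(a: Graph) -> Graph:
    return Graph(a.schema)


def _copy_left_nodes(out: Graph, a: Graph) -> None:
    out.nodes = {k: dict(v) for k, v in a.nodes.items()}
    out._adj = {k: set() for k in a.nodes}


def _set_link(out: Graph, key, rec) -> None:
    out.links[key] = rec
    out._adj[key[0]].add(key)
    out._adj[key[1]].add(key)


def _merged_node(a: Graph, b: Graph, name: str) -> dict:
    rec = merge_records(
        a.nodes[name],
        b.nodes[name],
        a.schema.node_type.attrs,
        b.schema.node_type.attrs,
    )
    rec[a.schema.node_type.name_attr] = name
    return rec


def _coerced_node(a: Graph, b: Graph, name: str) -> dict:
    rec = coerce_record(
        b.nodes[name], b.schema.node_type.attrs, a.schema.node_type.attrs
    )
    rec[a.schema.node_type.name_attr] = name
    return rec


def _merged_link(a: Graph, b: Graph, key) -> dict:
    return merge_records(
        a.links[key],
        b.links[key],
        a.schema.link_type.attrs,
        b.schema.link_type.attrs,
    )


def _coerced_link(a: Graph, b: Graph, key) -> dict:
    return coerce_record(
        b.links[key], b.schema.link_type.attrs, a.schema.link_type.attrs
    )


def dotted_add(a: Graph, b: Graph) -> Graph:
    """``A .+ B``: union of nodes and union of links."""
    _check_operands(a, b)
    out = _fresh(a)
    for name in a.nodes:
        out.nodes[name] = (
            _merged_node(a, b, name) if name in b.nodes else dict(a.nodes[name])
        )
        out._adj[name] = set()
    for name in b.nodes:
        if name not in out.nodes:
            out.nodes[name] = _coerced_node(a, b, name)
            out._adj[name] = set()
    for key in a.links:
        rec = _merged_link(a, b, key) if key in b.links else dict(a.links[key])
        _set_link(out, key, rec)
    for key in b.links:
        if key not in out.links:
            _set_link(out, key, _coerced_link(a, b, key))
    return out


def nondotted_add(a: Graph, b: Graph) -> Graph:
    """``A + B``: keep A's nodes; add B's links whose endpoints are already in A."""
    _check_operands(a, b)
    out = _fresh(a)
    _copy_left_nodes(out, a)
    for key in a.links:
        rec = _merged_link(a, b, key) if key in b.links else dict(a.links[key])
        _set_link(out, key, rec)
    for key in b.links:
        if key not in out.links and key[0] in a.nodes and key[1] in a.nodes:
            _set_link(out, key, _coerced_link(a, b, key))
    return out


def dotted_sub(a: Graph, b: Graph) -> Graph:
    """``A .- B``: nodes V_A \\ V_B; links of E_A \\ E_B with both endpoints surviving."""
    _check_operands(a, b)
    out = _fresh(a)
    for name in a.nodes:
        if name not in b.nodes:
            out.nodes[name] = dict(a.nodes[name])
            out._adj[name] = set()
    for key in a.links:
        if key not in b.links and key[0] in out.nodes and key[1] in out.nodes:
            _set_link(out, key, dict(a.links[key]))
    return out


def nondotted_sub(a: Graph, b: Graph) -> Graph:
    """``A - B``: keep A's nodes; remove B's links (identity = endpoint pair)."""
    _check_operands(a, b)
    out = _fresh(a)
    _copy_left_nodes(out, a)
    for key in a.links:
        if key not in b.links:
            _set_link(out, key, dict(a.links[key]))
    return out


def dotted_intersect(a: Graph, b: Graph) -> Graph:
    """``A .& B``: nodes V_A ∩ V_B; links E_A ∩ E_B; records merged."""
    _check_operands(a, b)
    out = _fresh(a)
    for name in a.nodes:
        if name in b.nodes:
            out.nodes[name] = _merged_node(a, b, name)
            out._adj[name] = set()
    for key in a.links:
        if key in b.links:
            _set_link(out, key, _merged_link(a, b, key))
    return out


def nondotted_intersect(a: Graph, b: Graph) -> Graph:
    """``A & B``: keep A's nodes; links E_A ∩ E_B."""
    _check_operands(a, b)
    out = _fresh(a)
    _copy_left_nodes(out, a)
    for key in a.links:
        if key in b.links:
            _set_link(out, key, _merged_link(a, b, key))
    return out


def _join(a: Graph, b: Graph, loops: bool) -> Graph:
    out = dotted_add(a, b)
    defaults = {s.name: s.default for s in a.schema.link_type.attrs}
    for vi in a.nodes:
        for vj in b.nodes:
            if vi == vj and not loops:
                continue
            key = out.canonical(vi, vj)
            # union semantics: an existing link keeps its attributes
            if key not in out.links:
                _set_link(out, key, dict(defaults))
    return out


def join_star(a: Graph, b: Graph) -> Graph:
    """``A * B``: union plus all cross links v_i∈V_A, v_j∈V_B with v_i ≠ v_j."""
    return _join(a, b, loops=False)


def join_double_star(a: Graph, b: Graph) -> Graph:
    """``A ** B``: as ``*`` but shared nodes also receive self-loops."""
    return _join(a, b, loops=True)


#: operator symbol -> implementation, shared by the DSL and the CLI
OPERATORS = {
    ".+": dotted_add,
    "+": nondotted_add,
    ".-": dotted_sub,
    "-": nondotted_sub,
    ".&": dotted_intersect,
    "&": nondotted_intersect,
    "*": join_star,
    "**": join_double_star,
}
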