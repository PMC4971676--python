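"""Typed attribute-graph data model.

A graph is a set of named nodes plus a set of links identified by endpoint
pairs.  Every node and link carries attribute values conforming to a declared
type: an ordered list of (name, primitive type, default) triples drawn from
the four primitives ``string``, ``int``, ``float`` and ``double``.  The first
attribute of a node type is always a string holding the node name.

Reserved visual attributes (underscore-prefixed) are appended automatically to
every declared type so that layout procedures can annotate any graph:
``_x,_y,_z`` (scene coordinates), ``_r,_g,_b`` (color in [0,1]), ``_radius``
and ``_label`` for nodes; ``_r,_g,_b`` and ``_width`` for links.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GraphWarning",
    "GraphError",
    "AttributeSpec",
    "NodeType",
    "LinkType",
    "GraphSchema",
    "Graph",
    "new_graph",
    "coerce_record",
    "NODE_VISUAL_ATTRS",
    "LINK_VISUAL_ATTRS",
]

PRIMITIVES = ("string", "int", "float", "double")

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class GraphWarning(UserWarning):
    """Non-fatal events: duplicate rows, last-wins overwrites, missing graphics."""


class GraphError(ValueError):
    """Schema, type or closure violations."""


def _zero(ptype: str):
    return "" if ptype == "string" else (0 if ptype == "int" else 0.0)


def _check_value(ptype: str, value):
    """Validate and normalize *value* for *ptype*; raise GraphError on mismatch."""
    if ptype == "string":
        if not isinstance(value, str):
            raise GraphError(f"expected string, got {value!r}")
        return value
    if ptype == "int":
        # bool is an int subclass but never a sensible attribute value
        if isinstance(value, bool) or not isinstance(value, int):
            raise GraphError(f"expected int, got {value!r}")
        return value
    # float and double share double-precision storage
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise GraphError(f"expected {ptype}, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class AttributeSpec:
    """One declared attribute: name, primitive type, default value."""

    name: str
    ptype: str
    default: object = None

    def __post_init__(self):
        if self.ptype not in PRIMITIVES:
            raise GraphError(f"unknown primitive type {self.ptype!r}")
        if not _IDENT_RE.match(self.name):
            raise GraphError(f"attribute name {self.name!r} is not an identifier")
        d = self.default if self.default is not None else _zero(self.ptype)
        object.__setattr__(self, "default", _check_value(self.ptype, d))


# Reserved visual attributes, appended to every user declaration.
NODE_VISUAL_ATTRS = (
    AttributeSpec("_x", "double", 0.0),
    AttributeSpec("_y", "double", 0.0),
    AttributeSpec("_z", "double", 0.0),
    AttributeSpec("_r", "double", 0.5),
    AttributeSpec("_g", "double", 0.5),
    AttributeSpec("_b", "double", 0.5),
    AttributeSpec("_radius", "double", 1.0),
    AttributeSpec("_label", "string", ""),
)
LINK_VISUAL_ATTRS = (
    AttributeSpec("_r", "double", 0.5),
    AttributeSpec("_g", "double", 0.5),
    AttributeSpec("_b", "double", 0.5),
    AttributeSpec("_width", "double", 1.0),
)


def _validate_attrs(attrs: tuple[AttributeSpec, ...], visual: tuple[AttributeSpec, ...]):
    seen = set()
    for a in attrs:
        if a.name.startswith("_"):
            raise GraphError(
                f"attribute name {a.name!r}: leading underscore is reserved for visual attributes"
            )
        if a.name in seen:
            raise GraphError(f"duplicate attribute name {a.name!r}")
        seen.add(a.name)
    return attrs + visual


@dataclass(frozen=True)
class NodeType:
    """Named node type; first attribute must be a string (the node name)."""

    name: str
    attrs: tuple[AttributeSpec, ...]

    def __post_init__(self):
        attrs = tuple(self.attrs)
        if not attrs:
            raise GraphError("node type needs at least one attribute (the name)")
        if attrs[0].ptype != "string":
            raise GraphError("first node attribute must be a string (the node name)")
        object.__setattr__(self, "attrs", _validate_attrs(attrs, NODE_VISUAL_ATTRS))

    @property
    def user_attrs(self) -> tuple[AttributeSpec, ...]:
        return tuple(a for a in self.attrs if not a.name.startswith("_"))

    @property
    def name_attr(self) -> str:
        return self.attrs[0].name


@dataclass(frozen=True)
class LinkType:
    """Named link type with a directedness flag; attrs may be empty."""

    name: str
    directed: bool = False
    attrs: tuple[AttributeSpec, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "attrs", _validate_attrs(tuple(self.attrs), LINK_VISUAL_ATTRS)
        )

    @property
    def user_attrs(self) -> tuple[AttributeSpec, ...]:
        return tuple(a for a in self.attrs if not a.name.startswith("_"))


@dataclass(frozen=True)
class GraphSchema:
    node_type: NodeType
    link_type: LinkType

    @property
    def directed(self) -> bool:
        return self.link_type.directed


def _defaults(attrs: Iterable[AttributeSpec]) -> dict:
    return {a.name: a.default for a in attrs}


def coerce_record(
    values: Mapping[str, object],
    source_attrs: Iterable[AttributeSpec],
    target_attrs: Iterable[AttributeSpec],
) -> dict:
    """Coerce a record between types (attribute promotion / restriction).

    Attributes are matched by (name, ptype): matched attributes copy their
    values, target attributes absent from the source take the target default,
    and source attributes absent from the target are dropped.  A shared name
    with a different primitive type is an error.
    """
    src = {a.name: a for a in source_attrs}
    out = {}
    for t in target_attrs:
        s = src.get(t.name)
        if s is None:
            out[t.name] = t.default
        elif s.ptype != t.ptype:
            raise GraphError(
                f"attribute {t.name!r}: cannot promote {s.ptype} to {t.ptype}"
            )
        else:
            out[t.name] = values.get(t.name, s.default)
    return out


class Graph:
    """A simple typed attribute graph.

    Nodes live in ``nodes`` (name -> attribute dict); links live in ``links``
    (canonical endpoint pair -> attribute dict).  For undirected link types
    the endpoint pair is stored lexicographically sorted, so (b, d) and (d, b)
    denote the same link.  The closure invariant — both endpoints of every
    link exist as nodes — holds after every mutation.
    """

    __slots__ = ("schema", "nodes", "links", "_adj")

    def __init__(self, schema: GraphSchema):
        self.schema = schema
        self.nodes: dict[str, dict] = {}
        self.links: dict[tuple[str, str], dict] = {}
        # node name -> set of incident link keys (self-loop appears once)
        self._adj: dict[str, set[tuple[str, str]]] = {}

    # -- basics ---------------------------------------------------------

    @property
    def directed(self) -> bool:
        return self.schema.directed

    def canonical(self, src: str, dst: str) -> tuple[str, str]:
        if self.directed or src <= dst:
            return (src, dst)
        return (dst, src)

    def __len__(self) -> int:
        return len(self.nodes)

    def n_links(self) -> int:
        return len(self.links)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.schema == other.schema
            and self.nodes == other.nodes
            and self.links == other.links
        )

    def copy(self) -> "Graph":
        g = Graph(self.schema)
        g.nodes = {k: dict(v) for k, v in self.nodes.items()}
        g.links = {k: dict(v) for k, v in self.links.items()}
        g._adj = {k: set(v) for k, v in self._adj.items()}
        return g

    # -- mutation -------------------------------------------------------

    def add_node(self, name: str, values: Mapping[str, object] | None = None,
                 _warn: bool = True) -> "Graph":
        """Add (or overwrite, last-wins) a node; missing attributes default."""
        if not name:
            raise GraphError("node name must be non-empty")
        nt = self.schema.node_type
        rec = _defaults(nt.attrs)
        rec[nt.name_attr] = name
        if values:
            declared = {a.name: a for a in nt.attrs}
            for k, v in values.items():
                a = declared.get(k)
                if a is None:
                    raise GraphError(f"undeclared node attribute {k!r}")
                rec[k] = _check_value(a.ptype, v)
            rec[nt.name_attr] = name
        if name in self.nodes:
            if _warn and self.nodes[name] != rec:
                warnings.warn(f"node {name!r} redefined (last-wins)", GraphWarning,
                              stacklevel=2)
        else:
            self._adj[name] = set()
        self.nodes[name] = rec
        return self

    def add_link(self, src: str, dst: str, values: Mapping[str, object] | None = None,
                 _warn: bool = True) -> "Graph":
        """Add (or overwrite) a link; absent endpoints are auto-created."""
        lt = self.schema.link_type
        rec = _defaults(lt.attrs)
        if values:
            declared = {a.name: a for a in lt.attrs}
            for k, v in values.items():
                a = declared.get(k)
                if a is None:
                    raise GraphError(f"undeclared link attribute {k!r}")
                rec[k] = _check_value(a.ptype, v)
        key = self.canonical(src, dst)
        if src not in self.nodes:
            self.add_node(src, _warn=_warn)
        if dst not in self.nodes:
            self.add_node(dst, _warn=_warn)
        if key in self.links:
            if _warn and self.links[key] != rec:
                warnings.warn(f"link {key} redefined (last-wins)", GraphWarning,
                              stacklevel=2)
        else:
            self._adj[src].add(key)
            self._adj[dst].add(key)
        self.links[key] = rec
        return self

    # -- queries --------------------------------------------------------

    def degree(self, name: str) -> int:
        """Number of incident links; a self-loop counts 1.

        For directed graphs this is in-degree + out-degree (each incident
        link counted once).
        """
        if name not in self.nodes:
            raise GraphError(f"unknown node {name!r}")
        return len(self._adj[name])

    def incident(self, name: str) -> frozenset[tuple[str, str]]:
        return frozenset(self._adj[name])

    def neighbors(self, name: str) -> set[str]:
        out = set()
        for a, b in self._adj[name]:
            out.add(b if a == name else a)
        out.discard(name)
        return out

    def validate(self) -> None:
        """Check the closure and canonicalization invariants; raise on breach."""
        for (a, b), _ in self.links.items():
            if a not in self.nodes or b not in self.nodes:
                raise GraphError(f"closure violated: link ({a!r},{b!r})")
            if not self.directed and a > b:
                raise GraphError(f"non-canonical undirected link key ({a!r},{b!r})")
        for name, rec in self.nodes.items():
            for spec in self.schema.node_type.attrs:
                if spec.name not in rec:
                    raise GraphError(f"node {name!r} missing attribute {spec.name!r}")


def new_graph(schema: GraphSchema) -> Graph:
    """Create an empty graph with the given schema."""
    return Graph(schema)


def simple_schema(
    node_attrs: Iterable[tuple] = (),
    link_attrs: Iterable[tuple] = (),
    directed: bool = False,
    node_name: str = "nt",
    link_name: str = "lt",
) -> GraphSchema:
    """Convenience schema builder from (name, ptype[, default]) tuples.

    The leading ``id: string`` name attribute is prepended automatically if
    the first declared node attribute is not a string.
    """
    nas = [AttributeSpec(*t) for t in node_attrs]
    if not nas or nas[0].ptype != "string":
        nas.insert(0, AttributeSpec("id", "string"))
    las = [AttributeSpec(*t) for t in link_attrs]
    return GraphSchema(
        NodeType(node_name, tuple(nas)), LinkType(link_name, directed, tuple(las))
    )
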