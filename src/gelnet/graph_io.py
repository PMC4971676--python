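"""Tabular (CSV/TSV) graph import/export and executable script serialization.

The tabular dialect lists node rows (name first, then declared attributes in
order), a single line containing only a hyphen, then link rows (source,
target, then link attributes in order).  Short rows fill trailing attributes
with declared defaults; there is no header row (a header will fail typed
parsing, loudly).  Exports are sorted so files are byte-stable across runs.

``save_script`` serializes a graph as a self-contained Gel-dialect script
(type declarations plus a graph literal); evaluating the script reconstructs
the graph exactly, including visual attributes, so a saved analysis replays
to the same picture.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

from .graph_model import AttributeSpec, Graph, GraphError, GraphSchema
from .lexer import quote_string

__all__ = [
    "TabularDialect",
    "import_tabular",
    "export_tabular",
    "save_script",
    "load_script",
]


@dataclass(frozen=True)
class TabularDialect:
    """Delimiter choice; the node/link separator is always a lone hyphen line."""

    delimiter: str = ","  # "," or "\t"

    def __post_init__(self):
        if self.delimiter not in (",", "\t"):
            raise GraphError("delimiter must be comma or tab")


CSV_DIALECT = TabularDialect(",")
TSV_DIALECT = TabularDialect("\t")


def _parse_cell(text: str, spec: AttributeSpec):
    try:
        if spec.ptype == "string":
            return text
        if spec.ptype == "int":
            return int(text)
        return float(text)
    except ValueError:
        raise GraphError(
            f"cannot parse {text!r} as {spec.ptype} for attribute {spec.name!r}"
        ) from None


def _render_cell(value) -> str:
    if isinstance(value, float):
        # float() strips numpy scalars; repr is the shortest round-trip form
        return repr(float(value))
    return str(value)


def _row_to_values(cells: list[str], attrs: tuple[AttributeSpec, ...],
                   what: str) -> dict:
    """Parse attribute *cells* against *attrs* in order; short rows default."""
    if len(cells) > len(attrs):
        raise GraphError(
            f"{what} row has {len(cells)} attribute columns but the schema "
            f"declares {len(attrs)}"
        )
    values = {}
    for spec, cell in zip(attrs, cells):
        values[spec.name] = _parse_cell(cell, spec)
    return values


def _split_rows(path: str, dialect: TabularDialect) -> tuple[list, list]:
    with open(path, encoding="utf-8", newline="") as fh:
        if dialect.delimiter == ",":
            rows = list(csv.reader(fh))
        else:
            rows = [line.rstrip("\n").split("\t") for line in fh]
    node_rows, link_rows, seen_sep = [], [], False
    for row in rows:
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) == 1 and row[0].strip() == "-":
            if seen_sep:
                raise GraphError("multiple hyphen separator lines")
            seen_sep = True
            continue
        (link_rows if seen_sep else node_rows).append(row)
    if not seen_sep:
        raise GraphError("missing hyphen separator line between nodes and links")
    return node_rows, link_rows


def import_tabular(
    path: str,
    schema: GraphSchema,
    dialect: TabularDialect = CSV_DIALECT,
    with_visual: bool = False,
) -> Graph:
    """Read a node-block/hyphen/link-block tabular file into a graph.

    With ``with_visual`` the columns after the user attributes are the
    reserved visual attributes (as written by ``export_tabular(...,
    with_visual=True)``).
    """
    node_rows, link_rows = _split_rows(path, dialect)
    g = Graph(schema)
    nattrs = _columns(schema.node_type.attrs, with_visual)
    lattrs = _columns(schema.link_type.attrs, with_visual)
    for row in node_rows:
        name = row[0]
        if not name:
            raise GraphError("empty node name in node block")
        values = _row_to_values(row[1:], nattrs[1:], "node")
        g.add_node(name, values)
    for row in link_rows:
        if len(row) < 2:
            raise GraphError(f"link row needs source and target: {row!r}")
        values = _row_to_values(row[2:], lattrs, "link")
        g.add_link(row[0], row[1], values)
    g.validate()
    return g


def _columns(attrs: tuple[AttributeSpec, ...], with_visual: bool):
    if with_visual:
        return attrs
    return tuple(a for a in attrs if not a.name.startswith("_"))


def export_tabular(
    g: Graph,
    path: str,
    dialect: TabularDialect = CSV_DIALECT,
    with_visual: bool = False,
) -> None:
    """Write the node block, a hyphen line, then the link block (both sorted).

    Visual (underscore) attributes are omitted unless requested: tabular
    export targets other programs, while visual state belongs to scripts.
    """
    nattrs = _columns(g.schema.node_type.attrs, with_visual)
    lattrs = _columns(g.schema.link_type.attrs, with_visual)
    buf = io.StringIO()
    if dialect.delimiter == ",":
        writer = csv.writer(buf, lineterminator="\n")
        emit = writer.writerow
    else:
        def emit(cells):
            for c in cells:
                if "\t" in c or "\n" in c:
                    raise GraphError(
                        f"value {c!r} contains a tab or newline; use the comma dialect"
                    )
            buf.write("\t".join(cells) + "\n")
    for name in sorted(g.nodes):
        rec = g.nodes[name]
        emit([name] + [_render_cell(rec[a.name]) for a in nattrs[1:]])
    emit(["-"])
    for key in sorted(g.links):
        rec = g.links[key]
        emit(list(key) + [_render_cell(rec[a.name]) for a in lattrs])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


# -- script serialization -------------------------------------------------


def _render_literal(value) -> str:
    if isinstance(value, str):
        return quote_string(value)
    return _render_cell(value)


def _decl(kind: str, tname: str, attrs, open_c: str, close_c: str) -> str:
    parts = []
    for a in attrs:
        if a.name.startswith("_"):
            continue
        s = f"{a.name}: {a.ptype}"
        zero = "" if a.ptype == "string" else (0 if a.ptype == "int" else 0.0)
        if a.default != zero:
            s += f" = {_render_literal(a.default)}"
        parts.append(s)
    return f"{kind} {tname}{open_c}{', '.join(parts)}{close_c};"


def _record_kvs(rec: dict, attrs, skip_names=()) -> str:
    parts = []
    for a in attrs:
        if a.name in skip_names:
            continue
        if rec[a.name] != a.default:
            parts.append(f"{a.name}={_render_literal(rec[a.name])}")
    return ", ".join(parts)


def save_script(g: Graph, path: str, name: str = "G") -> None:
    """Serialize *g* as a Gel-dialect script that rebuilds it exactly."""
    nt, lt = g.schema.node_type, g.schema.link_type
    lines = ["# gelnet graph script"]
    lines.append(_decl("nodetype", nt.name, nt.attrs, "(", ")"))
    if lt.directed:
        lines.append(_decl("linktype", lt.name, lt.attrs, "<", ">"))
    else:
        lines.append(_decl("linktype", lt.name, lt.attrs, "[", "]"))
    lines.append(f"graph {name}: {nt.name}, {lt.name} = {{")
    for node in sorted(g.nodes):
        kvs = _record_kvs(g.nodes[node], nt.attrs, skip_names=(nt.name_attr,))
        lines.append(f"  {quote_string(node)}({kvs});")
    arrow, oc, cc = ("->", "<", ">") if lt.directed else ("-", "[", "]")
    for key in sorted(g.links):
        kvs = _record_kvs(g.links[key], lt.attrs)
        src, dst = (quote_string(k) for k in key)
        lines.append(f"  {src} {arrow} {dst} {oc}{kvs}{cc};")
    lines.append("};")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_script(path: str) -> dict[str, Graph]:
    """Evaluate a Gel-dialect script file; return its graph bindings by name."""
    from .gel_dsl import run_script  # deferred: gel_dsl imports this module

    env = run_script(open(path, encoding="utf-8").read())
    return dict(env.graphs)
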