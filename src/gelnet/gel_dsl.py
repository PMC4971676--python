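"""Parser and evaluator for the Gel dialect, plus a small REPL.

The dialect covers typed node/link declarations, graph literals, the eight
graph operators with compound assignment, and the import/export/save/
select/foreach/list/help commands.  Concretely::

    nodetype ntA(id: string, count: int);
    linktype ltA[weight: double];          # [] undirected, <> directed
    graph A: ntA, ltA = {
      "a"(); "b"(count=2);
      "b" - "d" [weight=0.4];              # a -> b <...> for directed
    };
    C = A;                                  # coerces into C's declared type
    C .+= B;                                # compound operator assignment
    select H = A links where weight >= 0.5;
    foreach A nodes set _z := degree();
    foreach A links tally count, sum(weight);

All eight binary operators (``.+  +  .-  -  .&  &  *  **``) share one
precedence level and associate to the left, so chains such as ``G * G - G``
evaluate left-to-right exactly as written; parentheses override.  Statements
end with ``;``; ``#`` starts a comment.

Assigning into a graph declared with a wider type performs attribute
promotion, which is how the attributes of two heterogeneous graphs are both
preserved across a merge: declare the union type, assign the left graph,
then dotted-add the right one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from . import graph_io, query
from .algebra import OPERATORS, coerce_graph
from .expressions import Expr, parse_expression
from .graph_model import (
    AttributeSpec,
    Graph,
    GraphError,
    GraphSchema,
    LinkType,
    NodeType,
)
from .lexer import GelSyntaxError, Token, TokenStream, quote_string, tokenize

__all__ = ["parse_program", "print_program", "Env", "evaluate", "run_script", "repl"]

_ASSIGN_OPS = {"=", "+=", ".+=", "-=", ".-=", "&=", ".&=", "*=", "**="}
_BIN_OPS = {".+", "+", ".-", "-", ".&", "&", "*", "**"}
_PTYPES = {"string", "int", "float", "double"}


# -- AST -------------------------------------------------------------------

@dataclass(frozen=True)
class TypeDecl:
    kind: str  # "node" | "link"
    name: str
    directed: bool
    attrs: tuple  # of (name, ptype, default-or-None)
    line: int = field(default=0, compare=False)


@dataclass(frozen=True)
class NodeLit:
    name: str
    values: tuple  # of (attr, value)


@dataclass(frozen=True)
class LinkLit:
    src: str
    dst: str
    values: tuple
    directed: bool = False


@dataclass(frozen=True)
class GraphDecl:
    name: str
    node_type: str
    link_type: str
    literal: tuple | None  # of NodeLit | LinkLit
    line: int = field(default=0, compare=False)


@dataclass(frozen=True)
class GName:
    name: str
    line: int = field(default=0, compare=False)


@dataclass(frozen=True)
class GBinOp:
    op: str
    left: object
    right: object


@dataclass(frozen=True)
class Assign:
    name: str
    op: str
    expr: object
    line: int = field(default=0, compare=False)


@dataclass(frozen=True)
class Command:
    verb: str  # import | export | save | select | foreach | list | help
    args: dict
    line: int = field(default=0, compare=False)


# -- parsing ---------------------------------------------------------------

def _parse_literal_value(ts: TokenStream):
    neg = ts.accept_op("-") is not None
    t = ts.peek()
    if t.kind in ("INT", "REAL"):
        ts.next()
        return -t.value if neg else t.value
    if neg:
        raise GelSyntaxError(f"expected number after '-', found {t}", t.line, t.col)
    if t.kind == "STRING":
        ts.next()
        return t.value
    raise GelSyntaxError(f"expected literal value, found {t}", t.line, t.col)


def _parse_attr_list(ts: TokenStream, close: str) -> tuple:
    attrs = []
    if not ts.at_op(close):
        while True:
            name = ts.expect_ident().value
            ts.expect_op(":")
            t = ts.peek()
            ptype = ts.expect_ident(*_PTYPES).value
            default = None
            if ts.accept_op("="):
                default = _parse_literal_value(ts)
            attrs.append((name, ptype, default))
            if not ts.accept_op(","):
                break
    ts.expect_op(close)
    return tuple(attrs)


def _parse_name(ts: TokenStream) -> str:
    t = ts.peek()
    if t.kind == "STRING":
        ts.next()
        return t.value
    return ts.expect_ident().value


def _parse_kv_list(ts: TokenStream, close: str) -> tuple:
    out = []
    if not ts.at_op(close):
        while True:
            k = ts.expect_ident().value
            ts.expect_op("=")
            out.append((k, _parse_literal_value(ts)))
            if not ts.accept_op(","):
                break
    ts.expect_op(close)
    return tuple(out)


def _parse_graph_literal(ts: TokenStream) -> tuple:
    items = []
    ts.expect_op("{")
    while not ts.at_op("}"):
        name = _parse_name(ts)
        if ts.accept_op("("):
            items.append(NodeLit(name, _parse_kv_list(ts, ")")))
        elif ts.accept_op("->"):
            dst = _parse_name(ts)
            ts.expect_op("<")
            items.append(LinkLit(name, dst, _parse_kv_list(ts, ">"), True))
        elif ts.accept_op("-"):
            dst = _parse_name(ts)
            ts.expect_op("[")
            items.append(LinkLit(name, dst, _parse_kv_list(ts, "]"), False))
        else:
            t = ts.peek()
            raise GelSyntaxError(
                f"expected '(', '-' or '->' in graph literal, found {t}",
                t.line, t.col,
            )
        ts.expect_op(";")
    ts.expect_op("}")
    return tuple(items)


def _parse_graph_expr(ts: TokenStream):
    def term():
        if ts.accept_op("("):
            e = _parse_graph_expr(ts)
            ts.expect_op(")")
            return e
        t = ts.expect_ident()
        return GName(t.value, t.line)

    left = term()
    while ts.at_op(*_BIN_OPS):
        op = ts.next().value
        left = GBinOp(op, left, term())
    return left


def _parse_statement(ts: TokenStream):
    t = ts.peek()
    if t.kind != "IDENT":
        raise GelSyntaxError(f"expected statement, found {t}", t.line, t.col)
    word = t.value

    if word == "nodetype":
        ts.next()
        name = ts.expect_ident().value
        ts.expect_op("(")
        attrs = _parse_attr_list(ts, ")")
        ts.expect_op(";")
        return TypeDecl("node", name, False, attrs, t.line)

    if word == "linktype":
        ts.next()
        name = ts.expect_ident().value
        if ts.accept_op("["):
            attrs, directed = _parse_attr_list(ts, "]"), False
        elif ts.accept_op("<"):
            attrs, directed = _parse_attr_list(ts, ">"), True
        else:
            p = ts.peek()
            raise GelSyntaxError(
                f"expected '[' or '<' after link type name, found {p}", p.line, p.col
            )
        ts.expect_op(";")
        return TypeDecl("link", name, directed, attrs, t.line)

    if word == "graph":
        ts.next()
        name = ts.expect_ident().value
        ts.expect_op(":")
        nt = ts.expect_ident().value
        ts.expect_op(",")
        lt = ts.expect_ident().value
        literal = None
        if ts.accept_op("="):
            literal = _parse_graph_literal(ts)
        ts.expect_op(";")
        return GraphDecl(name, nt, lt, literal, t.line)

    if word == "import" or word == "export" or word == "save":
        ts.next()
        gname = ts.expect_ident().value
        p = ts.peek()
        if p.kind != "STRING":
            raise GelSyntaxError(f"expected file path string, found {p}", p.line, p.col)
        ts.next()
        args = {"graph": gname, "path": p.value}
        if word == "export" and ts.at_ident("visual"):
            ts.next()
            args["visual"] = True
        ts.expect_op(";")
        return Command(word, args, t.line)

    if word == "select":
        ts.next()
        dest = ts.expect_ident().value
        ts.expect_op("=")
        src = ts.expect_ident().value
        target = ts.expect_ident("nodes", "links").value
        ts.expect_ident("where")
        expr = parse_expression(ts)
        ts.expect_op(";")
        return Command(
            "select", {"dest": dest, "graph": src, "target": target, "where": expr},
            t.line,
        )

    if word == "foreach":
        ts.next()
        gname = ts.expect_ident().value
        target = ts.expect_ident("nodes", "links").value
        where = None
        if ts.at_ident("where"):
            ts.next()
            where = parse_expression(ts)
        mode = ts.expect_ident("set", "tally").value
        if mode == "set":
            assignments = []
            while True:
                attr = ts.expect_ident().value
                ts.expect_op(":=")
                assignments.append((attr, parse_expression(ts)))
                if not ts.accept_op(","):
                    break
            ts.expect_op(";")
            return Command(
                "foreach",
                {"graph": gname, "target": target, "where": where,
                 "set": tuple(assignments)},
                t.line,
            )
        reducers = []
        while True:
            kind = ts.expect_ident("count", "sum", "min", "max").value
            if kind == "count":
                reducers.append(("count", None))
            else:
                ts.expect_op("(")
                reducers.append((kind, parse_expression(ts)))
                ts.expect_op(")")
            if not ts.accept_op(","):
                break
        ts.expect_op(";")
        return Command(
            "foreach",
            {"graph": gname, "target": target, "where": where,
             "tally": tuple(reducers)},
            t.line,
        )

    if word in ("list", "help"):
        ts.next()
        ts.expect_op(";")
        return Command(word, {}, t.line)

    # assignment: IDENT assign_op graph_expr ;
    name_tok = ts.next()
    op_tok = ts.peek()
    if not (op_tok.kind == "OP" and op_tok.value in _ASSIGN_OPS):
        raise GelSyntaxError(
            f"expected an assignment operator after {word!r}, found {op_tok}",
            op_tok.line, op_tok.col,
        )
    ts.next()
    expr = _parse_graph_expr(ts)
    ts.expect_op(";")
    return Assign(word, op_tok.value, expr, name_tok.line)


def parse_program(text: str) -> list:
    ts = TokenStream(tokenize(text))
    stmts = []
    while ts.peek().kind != "EOF":
        stmts.append(_parse_statement(ts))
    return stmts


# -- pretty printing (parse . print round-trips) ---------------------------

def _print_value(v) -> str:
    if isinstance(v, str):
        return quote_string(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _print_expr(e: Expr) -> str:
    op = e.op
    if op == "lit":
        v = e.args[0]
        if v is True:
            return "true"
        if v is False:
            return "false"
        return _print_value(v)
    if op == "attr":
        return e.args[0]
    if op == "degree":
        return "degree()"
    if op == "neg":
        return f"(-{_print_expr(e.args[0])})"
    if op == "not":
        return f"(not {_print_expr(e.args[0])})"
    kind, l, r = e.args
    return f"({_print_expr(l)} {kind} {_print_expr(r)})"


def _print_gexpr(e) -> str:
    if isinstance(e, GName):
        return e.name
    return f"({_print_gexpr(e.left)} {e.op} {_print_gexpr(e.right)})"


def _print_kvs(values) -> str:
    return ", ".join(f"{k}={_print_value(v)}" for k, v in values)


def print_program(stmts: list) -> str:
    out = []
    for s in stmts:
        if isinstance(s, TypeDecl):
            parts = []
            for name, ptype, default in s.attrs:
                p = f"{name}: {ptype}"
                if default is not None:
                    p += f" = {_print_value(default)}"
                parts.append(p)
            body = ", ".join(parts)
            if s.kind == "node":
                out.append(f"nodetype {s.name}({body});")
            elif s.directed:
                out.append(f"linktype {s.name}<{body}>;")
            else:
                out.append(f"linktype {s.name}[{body}];")
        elif isinstance(s, GraphDecl):
            head = f"graph {s.name}: {s.node_type}, {s.link_type}"
            if s.literal is None:
                out.append(head + ";")
            else:
                out.append(head + " = {")
                for item in s.literal:
                    if isinstance(item, NodeLit):
                        out.append(
                            f"  {quote_string(item.name)}({_print_kvs(item.values)});"
                        )
                    elif item.directed:
                        out.append(
                            f"  {quote_string(item.src)} -> {quote_string(item.dst)} "
                            f"<{_print_kvs(item.values)}>;"
                        )
                    else:
                        out.append(
                            f"  {quote_string(item.src)} - {quote_string(item.dst)} "
                            f"[{_print_kvs(item.values)}];"
                        )
                out.append("};")
        elif isinstance(s, Assign):
            out.append(f"{s.name} {s.op} {_print_gexpr(s.expr)};")
        elif isinstance(s, Command):
            out.append(_print_command(s))
        else:
            raise AssertionError(f"unknown statement {s!r}")
    return "\n".join(out) + "\n"


def _print_command(s: Command) -> str:
    a = s.args
    if s.verb in ("import", "save"):
        return f"{s.verb} {a['graph']} {quote_string(a['path'])};"
    if s.verb == "export":
        vis = " visual" if a.get("visual") else ""
        return f"export {a['graph']} {quote_string(a['path'])}{vis};"
    if s.verb == "select":
        return (
            f"select {a['dest']} = {a['graph']} {a['target']} "
            f"where {_print_expr(a['where'])};"
        )
    if s.verb == "foreach":
        head = f"foreach {a['graph']} {a['target']}"
        if a["where"] is not None:
            head += f" where {_print_expr(a['where'])}"
        if "set" in a:
            body = ", ".join(f"{k} := {_print_expr(e)}" for k, e in a["set"])
            return f"{head} set {body};"
        parts = []
        for kind, e in a["tally"]:
            parts.append("count" if kind == "count" else f"{kind}({_print_expr(e)})")
        return f"{head} tally {', '.join(parts)};"
    return f"{s.verb};"


# -- evaluation ------------------------------------------------------------

@dataclass
class Env:
    """Evaluation environment: declared types and graph bindings."""

    types: dict = field(default_factory=dict)
    graphs: dict = field(default_factory=dict)
    declared_schema: dict = field(default_factory=dict)
    output: Callable[[str], None] = print
    last_tally: list | None = None


def _eval_gexpr(e, env: Env) -> Graph:
    if isinstance(e, GName):
        g = env.graphs.get(e.name)
        if g is None:
            raise GraphError(f"undeclared graph {e.name!r} (line {e.line})")
        return g
    left = _eval_gexpr(e.left, env)
    right = _eval_gexpr(e.right, env)
    return OPERATORS[e.op](left, right)


def _literal_dialect(path: str) -> graph_io.TabularDialect:
    return graph_io.TSV_DIALECT if path.endswith((".tsv", ".tab")) else graph_io.CSV_DIALECT


HELP_TEXT = """\
Gel dialect quick reference
  nodetype N(name: string, ...);        declare a node type (first attr: string name)
  linktype L[...];  linktype L<...>;    undirected / directed link type
  graph G: N, L;  graph G: N, L = {...};declare a graph, optionally with a literal
  G = expr;  G .+= H;  G += H; ...      assignment and compound assignment
  operators: .+  +  .-  -  .&  &  *  ** (equal precedence, left associative)
    .+ union of nodes and links          +  add links between existing nodes
    .- remove nodes (and their links)    -  remove links only
    .& node and link intersection        &  link intersection, keep nodes
    *  join with all cross links         ** join incl. self-loops on shared nodes
  import G "file.csv";                  read tabular graph (schema from G's declaration)
  export G "file.csv" [visual];         write tabular graph
  save G "file.gel";                    write an executable script that rebuilds G
  select H = G nodes where <expr>;      induced subgraph of matching nodes
  select H = G links where <expr>;      matching links plus their endpoints
  foreach G nodes [where e] set a := e; map attribute values (snapshot semantics)
  foreach G links tally count, sum(e), min(e), max(e);
  list;                                 show loaded graphs
  help;                                 this text
"""


def _exec_statement(s, env: Env) -> None:
    if isinstance(s, TypeDecl):
        attrs = tuple(AttributeSpec(n, p, d) for n, p, d in s.attrs)
        if s.kind == "node":
            env.types[s.name] = NodeType(s.name, attrs)
        else:
            env.types[s.name] = LinkType(s.name, s.directed, attrs)
        return

    if isinstance(s, GraphDecl):
        nt = env.types.get(s.node_type)
        lt = env.types.get(s.link_type)
        if not isinstance(nt, NodeType):
            raise GraphError(f"undeclared node type {s.node_type!r}")
        if not isinstance(lt, LinkType):
            raise GraphError(f"undeclared link type {s.link_type!r}")
        schema = GraphSchema(nt, lt)
        g = Graph(schema)
        for item in s.literal or ():
            if isinstance(item, NodeLit):
                g.add_node(item.name, dict(item.values))
            else:
                g.add_link(item.src, item.dst, dict(item.values))
        env.declared_schema[s.name] = schema
        env.graphs[s.name] = g
        return

    if isinstance(s, Assign):
        if s.op == "=":
            result = _eval_gexpr(s.expr, env)
            schema = env.declared_schema.get(s.name)
            if schema is not None and schema != result.schema:
                result = coerce_graph(result, schema)
            else:
                result = result.copy()
            env.graphs[s.name] = result
            return
        current = env.graphs.get(s.name)
        if current is None:
            raise GraphError(f"undeclared graph {s.name!r} (line {s.line})")
        right = _eval_gexpr(s.expr, env)
        env.graphs[s.name] = OPERATORS[s.op[:-1]](current, right)
        return

    assert isinstance(s, Command)
    a = s.args
    if s.verb == "help":
        env.output(HELP_TEXT)
        return
    if s.verb == "list":
        if not env.graphs:
            env.output("(no graphs loaded)")
        for name, g in env.graphs.items():
            nattrs = ", ".join(x.name for x in g.schema.node_type.user_attrs)
            lattrs = ", ".join(x.name for x in g.schema.link_type.user_attrs)
            env.output(
                f"{name}: {len(g)} nodes, {g.n_links()} links"
                f" | node attrs: {nattrs or 'none'} | link attrs: {lattrs or 'none'}"
            )
        return

    if s.verb in ("import", "export", "save"):
        gname = a["graph"]
        if s.verb == "import":
            schema = env.declared_schema.get(gname)
            if schema is None:
                raise GraphError(
                    f"graph {gname!r} must be declared with a schema before import"
                )
            env.graphs[gname] = graph_io.import_tabular(
                a["path"], schema, _literal_dialect(a["path"])
            )
            return
        g = env.graphs.get(gname)
        if g is None:
            raise GraphError(f"undeclared graph {gname!r}")
        if s.verb == "export":
            graph_io.export_tabular(
                g, a["path"], _literal_dialect(a["path"]),
                with_visual=bool(a.get("visual")),
            )
        else:
            graph_io.save_script(g, a["path"], name=gname)
        return

    if s.verb == "select":
        g = env.graphs.get(a["graph"])
        if g is None:
            raise GraphError(f"undeclared graph {a['graph']!r}")
        if a["target"] == "nodes":
            env.graphs[a["dest"]] = query.select_nodes(
                g, query.Predicate("node", a["where"])
            )
        else:
            env.graphs[a["dest"]] = query.select_links(
                g, query.Predicate("link", a["where"])
            )
        return

    if s.verb == "foreach":
        g = env.graphs.get(a["graph"])
        if g is None:
            raise GraphError(f"undeclared graph {a['graph']!r}")
        target = "node" if a["target"] == "nodes" else "link"
        pred = query.Predicate(target, a["where"]) if a["where"] is not None else None
        if "set" in a:
            env.graphs[a["graph"]] = query.foreach_update(
                g, target, list(a["set"]), pred
            )
        else:
            env.last_tally = query.foreach_tally(g, target, list(a["tally"]), pred)
            env.output("  ".join(_print_value(v) for v in env.last_tally))
        return

    raise AssertionError(f"unknown command {s.verb!r}")


def evaluate(stmts: list, env: Env | None = None) -> Env:
    """Execute parsed statements top to bottom against *env*."""
    env = env or Env()
    for s in stmts:
        try:
            _exec_statement(s, env)
        except (GraphError, OSError) as exc:
            line = getattr(s, "line", 0)
            raise GraphError(f"line {line}: {exc}") from exc
    return env


def run_script(text: str, env: Env | None = None) -> Env:
    """Parse and evaluate a script; returns the final environment."""
    return evaluate(parse_program(text), env)


def repl(input_fn=input, output_fn=print) -> Env:
    """Line-by-line evaluation with a persistent environment.

    Statements may span lines; a statement is executed once its braces are
    balanced and it ends with ``;``.  Errors are printed and the session
    continues with prior bindings intact.
    """
    env = Env(output=output_fn)
    output_fn("gelnet Gel dialect — 'help;' lists commands, Ctrl-D exits")
    buf: list[str] = []
    while True:
        try:
            line = input_fn("gel> " if not buf else "...> ")
        except EOFError:
            break
        buf.append(line)
        text = "\n".join(buf)
        stripped = text.split("#")[0].rstrip()
        if stripped and not stripped.endswith(";"):
            continue
        if stripped.count("{") > stripped.count("}"):
            continue
        buf = []
        if not stripped:
            continue
        try:
            evaluate(parse_program(text), env)
        except (GelSyntaxError, GraphError) as exc:
            output_fn(f"error: {exc}")
    return env
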