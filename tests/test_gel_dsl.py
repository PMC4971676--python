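"""Lexing, parsing, evaluation and REPL behavior of the Gel dialect."""

import pytest

from gelnet.algebra import dotted_add
from gelnet.gel_dsl import (
    Env,
    HELP_TEXT,
    evaluate,
    parse_program,
    print_program,
    repl,
    run_script,
)
from gelnet.graph_model import GraphError
from gelnet.lexer import GelSyntaxError, tokenize
from gelnet.synthetic import gen_worked_example_pair

EXAMPLE_SCRIPT = """
nodetype ntA(id: string, count: int);
nodetype ntB(id: string, tag: string);
linktype ltA[weight: double];
graph A: ntA, ltA = {
  a(); b(); c(); d();
  a - b []; b - c []; b - d [weight=0.4];
};
graph B: ntB, ltA = {
  b(); d(tag="T"); e(tag="E");
  b - d [weight=0.3]; d - e [];
};
"""


# -- lexer ----------------------------------------------------------------

def test_tokenize_dotted_operator_with_and_without_spaces():
    spaced = [(t.kind, t.value) for t in tokenize("A .+ B")]
    tight = [(t.kind, t.value) for t in tokenize("A.+B")]
    assert spaced == tight
    assert spaced[:3] == [("IDENT", "A"), ("OP", ".+"), ("IDENT", "B")]


def test_tokenize_real_literal_vs_dotted_operator():
    assert [(t.kind, t.value) for t in tokenize("0.4")][0] == ("REAL", 0.4)
    # a dot after a complete number resumes operator lexing
    kinds = [(t.kind, t.value) for t in tokenize("1.+2")]
    assert kinds[:3] == [("INT", 1), ("OP", ".+"), ("INT", 2)]
    # leading-dot real at expression start
    assert [(t.kind, t.value) for t in tokenize(".5")][0] == ("REAL", 0.5)


def test_tokenize_errors_carry_position():
    with pytest.raises(GelSyntaxError) as err:
        tokenize('x = "unterminated\n')
    assert "line 1" in str(err.value)
    with pytest.raises(GelSyntaxError):
        tokenize("a ~ b")


def test_comments_are_stripped():
    toks = tokenize("A # the rest is ignored .+ B\n;")
    assert [t.kind for t in toks] == ["IDENT", "OP", "EOF"]


# -- parser ---------------------------------------------------------------

def test_parse_type_declaration_attribute_count():
    (decl,) = parse_program("nodetype nt(id: string, count: int);")
    assert decl.kind == "node" and len(decl.attrs) == 2


def test_parse_directed_vs_undirected_link_types():
    undirected, directed = parse_program(
        "linktype lu[w: double]; linktype ld<w: double>;"
    )
    assert not undirected.directed and directed.directed


def test_operator_chain_parses_as_left_fold():
    (stmt,) = parse_program("G = A .+ B .+ C;")
    e = stmt.expr
    assert e.op == ".+" and e.left.op == ".+"
    assert e.left.left.name == "A" and e.left.right.name == "B" and e.right.name == "C"


def test_all_operators_share_one_precedence_level():
    (stmt,) = parse_program("G = A * A - A;")
    assert stmt.expr.op == "-" and stmt.expr.left.op == "*"


def test_parentheses_override_associativity():
    (stmt,) = parse_program("G = A .+ (B .+ C);")
    assert stmt.expr.op == ".+" and stmt.expr.right.op == ".+"


def test_syntax_error_names_the_line():
    with pytest.raises(GelSyntaxError) as err:
        parse_program("graph G: nt, lt = {\n  a(;\n};")
    assert "line 2" in str(err.value)


def test_parse_print_roundtrip():
    text = EXAMPLE_SCRIPT + (
        "graph C: ntA, ltA;\nC = A;\nC .+= B;\n"
        "select H = C links where weight >= 0.5 and not (weight > 2);\n"
        "foreach C nodes where degree() >= 1 set _z := degree(), _x := -1.5;\n"
        "foreach C links tally count, sum(weight), max(weight);\n"
        "export C \"out.csv\" visual;\nsave C \"out.gel\";\nlist;\nhelp;\n"
    )
    ast = parse_program(text)
    assert parse_program(print_program(ast)) == ast


# -- evaluation -----------------------------------------------------------

def test_promotion_idiom_preserves_both_attribute_sets():
    script = EXAMPLE_SCRIPT + """
nodetype ntC(id: string, count: int, tag: string);
graph C: ntC, ltA;
C = A;
C .+= B;
"""
    env = run_script(script)
    c = env.graphs["C"]
    assert [a.name for a in c.schema.node_type.user_attrs] == ["id", "count", "tag"]
    assert c.links[("b", "d")]["weight"] == 0.4
    assert c.nodes["e"]["count"] == 0 and c.nodes["e"]["tag"] == "E"
    assert c.nodes["d"]["tag"] == "T"


def test_declarations_only_produce_no_graphs():
    env = run_script("nodetype nt(id: string); linktype lt[];")
    assert env.types and not env.graphs


def test_compound_assignment_matches_direct_algebra_call():
    env = run_script(EXAMPLE_SCRIPT + "A .+= B;")
    a, b = gen_worked_example_pair()
    direct = dotted_add(a, b)
    rebound = env.graphs["A"]
    assert set(rebound.nodes) == set(direct.nodes)
    assert set(rebound.links) == set(direct.links)
    assert rebound.links[("b", "d")]["weight"] == 0.4
    # the right operand is unchanged
    assert set(env.graphs["B"].nodes) == {"b", "d", "e"}


def test_dsl_operators_match_algebra_module():
    from gelnet.algebra import OPERATORS

    a, b = gen_worked_example_pair()
    for op, fn in OPERATORS.items():
        env = run_script(EXAMPLE_SCRIPT + f"G = A {op} B;")
        got = env.graphs["G"]
        want = fn(env.graphs["A"], env.graphs["B"])
        assert got == want, op


def test_undeclared_name_is_an_error_with_location():
    with pytest.raises(GraphError) as err:
        run_script("nodetype nt(id: string); linktype lt[];\nG = H .+ H;")
    assert "H" in str(err.value) and "line 2" in str(err.value)


def test_evaluation_stops_at_failing_statement():
    env = Env(output=lambda s: None)
    with pytest.raises(GraphError):
        run_script(EXAMPLE_SCRIPT + "X = A .+ Missing;\nY = A;", env)
    assert "A" in env.graphs and "Y" not in env.graphs


# -- REPL -----------------------------------------------------------------

def _scripted_repl(lines):
    lines = iter(lines)
    out = []

    def fake_input(prompt):
        try:
            return next(lines)
        except StopIteration:
            raise EOFError

    env = repl(input_fn=fake_input, output_fn=out.append)
    return env, out


def test_repl_list_shows_loaded_graph_sizes():
    env, out = _scripted_repl([
        "nodetype nt(id: string);",
        "linktype lt[];",
        "graph G: nt, lt = { a(); a - b []; };",
        "list;",
    ])
    listing = [line for line in out if line.startswith("G:")]
    assert listing and "2 nodes" in listing[0] and "1 links" in listing[0]


def test_repl_error_keeps_prior_bindings():
    env, out = _scripted_repl([
        "nodetype nt(id: string);",
        "linktype lt[];",
        "graph G: nt, lt;",
        "G = G .+ Missing;",
        "list;",
    ])
    assert any(line.startswith("error:") for line in out)
    assert "G" in env.graphs


def test_repl_multiline_statement_and_help_lists_all_operators():
    env, out = _scripted_repl([
        "nodetype nt(id: string);",
        "linktype lt[];",
        "graph G: nt, lt = {",
        "  a();",
        "};",
        "help;",
    ])
    assert "G" in env.graphs
    helptext = "\n".join(out)
    for op in (".+", "+", ".-", "-", ".&", "&", "*", "**"):
        assert op in helptext
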