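"""The eight operators: worked examples, merge policy, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelnet.algebra import (
    OPERATORS,
    dotted_add,
    dotted_intersect,
    dotted_sub,
    join_double_star,
    join_star,
    merge_records,
    nondotted_add,
    nondotted_intersect,
    nondotted_sub,
)
from gelnet.graph_model import AttributeSpec, Graph, GraphError, simple_schema

from conftest import link_set, node_set, oracle_sets, random_graph


# -- merge policy ----------------------------------------------------------

WEIGHT_ATTRS = (AttributeSpec("weight", "double"),)


def test_left_value_wins_on_conflict():
    merged = merge_records({"weight": 0.4}, {"weight": 0.3}, WEIGHT_ATTRS, WEIGHT_ATTRS)
    assert merged["weight"] == 0.4


def test_left_default_is_overridden_by_right():
    merged = merge_records({"weight": 0.0}, {"weight": 0.3}, WEIGHT_ATTRS, WEIGHT_ATTRS)
    assert merged["weight"] == 0.3


def test_default_exception_requires_right_to_declare_the_attribute():
    # right side declares no 'weight', so the left default stays
    merged = merge_records({"weight": 0.0}, {}, WEIGHT_ATTRS, ())
    assert merged["weight"] == 0.0


def test_merge_identity():
    rec = {"weight": 0.7}
    assert merge_records(rec, rec, WEIGHT_ATTRS, WEIGHT_ATTRS) == rec


@given(
    left=st.floats(-2, 2, allow_nan=False),
    right=st.floats(-2, 2, allow_nan=False),
    default=st.floats(-2, 2, allow_nan=False),
)
@settings(max_examples=100, deadline=None)
def test_merge_precedence_property(left, right, default):
    attrs = (AttributeSpec("w", "double", default),)
    merged = merge_records({"w": left}, {"w": right}, attrs, attrs)
    assert merged["w"] == (right if left == default else left)


# -- worked example: graphs A and B ---------------------------------------

def test_dotted_add_example(worked_pair):
    a, b = worked_pair
    c = dotted_add(a, b)
    assert len(c) == 5 and c.n_links() == 4
    assert c.links[("b", "d")]["weight"] == 0.4
    assert c.nodes["e"]["count"] == 0  # default filled during promotion
    c.validate()


def test_dotted_add_identity_and_idempotence(worked_pair):
    a, _ = worked_pair
    empty = Graph(a.schema)
    assert dotted_add(a, empty) == a
    assert dotted_add(a, a) == a


def test_nondotted_add_keeps_left_nodes(worked_pair):
    a, b = worked_pair
    c = nondotted_add(a, b)
    assert node_set(c) == {"a", "b", "c", "d"}
    assert link_set(c) == {("a", "b"), ("b", "c"), ("b", "d")}
    assert nondotted_add(a, Graph(a.schema)) == a
    assert len(nondotted_add(Graph(a.schema), b)) == 0


def test_dotted_sub_drops_nodes_and_their_links(worked_pair):
    a, b = worked_pair
    c = dotted_sub(a, b)
    assert node_set(c) == {"a", "c"}
    assert link_set(c) == set()
    assert len(dotted_sub(a, a)) == 0
    assert dotted_sub(a, Graph(a.schema)) == a


def test_nondotted_sub_removes_links_only(worked_pair):
    a, b = worked_pair
    c = nondotted_sub(a, b)
    assert node_set(c) == {"a", "b", "c", "d"}
    assert link_set(c) == {("a", "b"), ("b", "c")}
    assert link_set(nondotted_sub(a, a)) == set()
    assert node_set(nondotted_sub(a, a)) == node_set(a)


def test_dotted_intersect_merges_attributes(worked_pair):
    a, b = worked_pair
    c = dotted_intersect(a, b)
    assert node_set(c) == {"b", "d"}
    assert link_set(c) == {("b", "d")}
    assert c.links[("b", "d")]["weight"] == 0.4  # left precedence
    assert dotted_intersect(a, a) == a
    assert len(dotted_intersect(a, Graph(a.schema))) == 0


def test_nondotted_intersect_keeps_left_nodes(worked_pair):
    a, b = worked_pair
    c = nondotted_intersect(a, b)
    assert node_set(c) == {"a", "b", "c", "d"}
    assert link_set(c) == {("b", "d")}
    assert nondotted_intersect(a, a) == a


def test_join_star_cross_links(worked_pair):
    a, b = worked_pair
    c = join_star(a, b)
    assert link_set(c) == {
        ("a", "b"), ("a", "d"), ("a", "e"), ("b", "c"), ("b", "d"),
        ("b", "e"), ("c", "d"), ("c", "e"), ("d", "e"),
    }
    # pre-existing links keep their attributes; new cross links default
    assert c.links[("b", "d")]["weight"] == 0.4
    assert c.links[("a", "e")]["weight"] == 0.0


def test_inverse_graph_identity(worked_pair):
    a, _ = worked_pair
    inv = nondotted_sub(join_star(a, a), a)
    assert link_set(inv) == {("a", "c"), ("a", "d"), ("c", "d")}
    n, e = len(a), a.n_links()
    assert inv.n_links() == n * (n - 1) // 2 - e


def test_join_double_star_adds_self_loops_for_shared_nodes(worked_pair):
    a, b = worked_pair
    c = join_double_star(a, b)
    assert c.n_links() == 11
    assert link_set(c) - link_set(join_star(a, b)) == {("b", "b"), ("d", "d")}
    empty = Graph(a.schema)
    assert node_set(join_double_star(empty, a)) == node_set(a)
    assert link_set(join_double_star(empty, a)) == link_set(a)


def test_mixing_directedness_is_an_error(worked_pair):
    a, _ = worked_pair
    directed = Graph(simple_schema(link_attrs=[("weight", "double")], directed=True))
    with pytest.raises(GraphError):
        dotted_add(a, directed)


def test_operators_do_not_mutate_operands(worked_pair):
    a, b = worked_pair
    before_a, before_b = a.copy(), b.copy()
    for op in OPERATORS.values():
        op(a, b)
    assert a == before_a and b == before_b


def test_chaining_is_a_left_fold(worked_pair):
    a, b = worked_pair
    c = Graph(a.schema).add_link("x", "y")
    chained = dotted_add(dotted_add(a, b), c)
    assert node_set(chained) == node_set(a) | node_set(b) | {"x", "y"}


# -- oracle equivalence ----------------------------------------------------

@pytest.mark.parametrize("op", sorted(OPERATORS))
def test_operator_matches_bruteforce_oracle(op):
    """(V, E) of each operator equals independent set arithmetic, 100 pairs."""
    rng = np.random.default_rng(20)
    fn = OPERATORS[op]
    for _ in range(100):
        a = random_graph(rng)
        b = random_graph(rng)
        result = fn(a, b)
        ev, ee = oracle_sets(op, node_set(a), link_set(a), node_set(b), link_set(b))
        assert node_set(result) == ev
        assert link_set(result) == ee
        result.validate()


def test_intersection_containment_property():
    """A .& B's link set is always within A & B's link set."""
    rng = np.random.default_rng(21)
    for _ in range(50):
        a, b = random_graph(rng), random_graph(rng)
        assert link_set(dotted_intersect(a, b)) <= link_set(nondotted_intersect(a, b))
        assert link_set(dotted_intersect(dotted_add(a, b), a)) >= link_set(a)
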