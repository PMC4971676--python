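"""Shared fixtures: the worked two-graph example, random graphs, and an
independent brute-force set-arithmetic oracle for the eight operators."""

from __future__ import annotations

import numpy as np
import pytest

from gelnet.graph_model import Graph, simple_schema
from gelnet.synthetic import gen_worked_example_pair

NAMES = list("abcdefghijkl")  # ≤ 12 nodes for oracle-sized graphs

WEIGHTED_SCHEMA = simple_schema(
    node_attrs=[("id", "string"), ("count", "int")],
    link_attrs=[("weight", "double")],
)


@pytest.fixture
def worked_pair():
    return gen_worked_example_pair()


def random_graph(rng: np.random.Generator, max_nodes: int = 12,
                 max_links: int = 30, schema=WEIGHTED_SCHEMA) -> Graph:
    """A random simple undirected graph with random attribute values."""
    g = Graph(schema)
    n = int(rng.integers(0, max_nodes + 1))
    nodes = list(rng.choice(NAMES, size=n, replace=False)) if n else []
    for name in nodes:
        g.add_node(name, {"count": int(rng.integers(0, 5))})
    if nodes:
        for _ in range(int(rng.integers(0, max_links + 1))):
            u, v = rng.choice(nodes, size=2)
            g.add_link(str(u), str(v), {"weight": float(rng.uniform(-1, 1))},
                       _warn=False)
    return g


def node_set(g: Graph) -> set:
    return set(g.nodes)


def link_set(g: Graph) -> set:
    return set(g.links)


def oracle_sets(op: str, va: set, ea: set, vb: set, eb: set) -> tuple[set, set]:
    """Brute-force (V, E) for each operator using plain set arithmetic.

    Link keys are canonical (sorted) endpoint pairs; cross products are
    enumerated exhaustively.  Independent of the Graph implementation.
    """
    def canon(u, v):
        return (u, v) if u <= v else (v, u)

    if op == ".+":
        return va | vb, ea | eb
    if op == "+":
        return set(va), ea | {(u, v) for (u, v) in eb if u in va and v in va}
    if op == ".-":
        keep = va - vb
        return keep, {(u, v) for (u, v) in ea - eb if u in keep and v in keep}
    if op == "-":
        return set(va), ea - eb
    if op == ".&":
        return va & vb, ea & eb
    if op == "&":
        return set(va), ea & eb
    cross = {canon(u, v) for u in va for v in vb if op == "**" or u != v}
    return va | vb, ea | eb | cross
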