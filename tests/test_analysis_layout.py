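"""Crown-plot, hub extraction, layering, bipartite/force layouts, overlay."""

import math

import numpy as np
import pytest

from gelnet import analysis_layout as al
from gelnet.graph_model import Graph, GraphError, simple_schema
from gelnet.synthetic import GeneratorConfig, gen_expression_table

SCHEMA = simple_schema(link_attrs=[("weight", "double")])


def cycle4():
    g = Graph(SCHEMA)
    for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]:
        g.add_link(u, v)
    return g


def star(n, hub="h"):
    g = Graph(SCHEMA)
    for i in range(n):
        g.add_link(hub, f"leaf{i}")
    return g


def test_crown_plot_circle_and_z():
    out = al.crown_plot(cycle4(), hub_threshold=3, rng_seed=0)
    for i, name in enumerate(sorted(out.nodes)):
        rec = out.nodes[name]
        angle = 2 * math.pi * i / 4
        assert rec["_x"] == pytest.approx(math.cos(angle), abs=1e-12)
        assert rec["_y"] == pytest.approx(math.sin(angle), abs=1e-12)
        assert math.hypot(rec["_x"], rec["_y"]) == pytest.approx(1.0, abs=1e-9)
        assert rec["_z"] == 2.0
        assert rec["_label"] == ""  # nobody reaches the threshold


def test_crown_plot_emphasizes_hubs():
    out = al.crown_plot(star(5), hub_threshold=3, rng_seed=1)
    emphasized = [n for n, r in out.nodes.items() if r["_label"]]
    assert emphasized == ["h"]
    assert out.nodes["h"]["_label"] == "h (5)"
    assert out.nodes["h"]["_radius"] == 2.0
    assert out.nodes["leaf0"]["_radius"] == 1.0


def test_crown_plot_seed_determinism_and_link_bleed():
    g = star(3)
    a = al.crown_plot(g, 3, rng_seed=42)
    b = al.crown_plot(g, 3, rng_seed=42)
    assert a == b
    other = al.crown_plot(g, 3, rng_seed=43)
    assert any(
        a.nodes[n]["_r"] != other.nodes[n]["_r"] for n in a.nodes
    )
    # each link takes the color of its higher-z endpoint (the hub)
    hub_color = (a.nodes["h"]["_r"], a.nodes["h"]["_g"], a.nodes["h"]["_b"])
    for rec in a.links.values():
        assert (rec["_r"], rec["_g"], rec["_b"]) == hub_color


def test_crown_plot_topology_untouched_and_errors():
    g = cycle4()
    out = al.crown_plot(g, 3, 0)
    assert set(out.nodes) == set(g.nodes) and set(out.links) == set(g.links)
    with pytest.raises(GraphError):
        al.crown_plot(Graph(SCHEMA), 3)
    with pytest.raises(GraphError):
        al.crown_plot(g, 0)


def test_extract_hub_subnet_star_and_path():
    s = star(5)
    sub = al.extract_hub_subnet(s, 5)
    assert set(sub.nodes) == set(s.nodes) and set(sub.links) == set(s.links)
    path = Graph(SCHEMA).add_link("a", "b").add_link("b", "c")
    assert len(al.extract_hub_subnet(path, 3)) == 0


def test_extract_hub_subnet_two_disjoint_stars():
    g = Graph(SCHEMA)
    for i in range(4):
        g.add_link("h1", f"x{i}")
    for i in range(3):
        g.add_link("h2", f"y{i}")
    sub = al.extract_hub_subnet(g, 3)  # both hubs qualify
    assert set(sub.nodes) == set(g.nodes) and set(sub.links) == set(g.links)
    sub.validate()


def test_assign_layers_inbetweener_definition():
    g = Graph(SCHEMA)
    g.add_link("m", "h1")
    g.add_link("m", "h2")
    g.add_link("o", "h1")
    out = al.assign_layers(g, {"h1", "h2"})
    assert out.nodes["m"]["_z"] == 2.0  # non-hub touching two hubs
    assert out.nodes["o"]["_z"] == 0.0  # only one hub neighbor
    assert out.nodes["h1"]["_z"] == 1.0


def test_assign_layers_hub_status_wins_and_spacing():
    g = Graph(SCHEMA)
    for other in ("h2", "h3", "h4"):
        g.add_link("h1", other)
    out = al.assign_layers(g, {"h1", "h2", "h3", "h4"}, spacing=2.5)
    assert out.nodes["h1"]["_z"] == 2.5  # a hub adjacent to 3 hubs stays a hub
    assert {r["_z"] for r in out.nodes.values()} == {2.5}
    with pytest.raises(GraphError):
        al.assign_layers(g, {"nope"})


def test_assign_layers_matches_bruteforce_hub_neighbor_scan():
    rng = np.random.default_rng(5)
    from conftest import random_graph

    for _ in range(20):
        g = random_graph(rng)
        if not g.nodes:
            continue
        hubs = {n for n in g.nodes if g.degree(n) >= 2}
        out = al.assign_layers(g, hubs)
        for name in g.nodes:
            n_hub_neighbors = sum(
                1
                for (u, v) in g.links
                if (u == name and v in hubs and v != name)
                or (v == name and u in hubs and u != name)
            )
            expected = 1.0 if name in hubs else (2.0 if n_hub_neighbors >= 2 else 0.0)
            assert out.nodes[name]["_z"] == expected


def test_bipartite_layout_columns_and_centering():
    g = Graph(SCHEMA)
    for n in ("l1", "l2", "r1", "r2", "r3"):
        g.add_node(n)
    out = al.bipartite_layout(g, {"l1", "l2"}, {"r1", "r2", "r3"})
    xs = sorted(rec["_x"] for rec in out.nodes.values())
    assert xs == [-1.0, -1.0, 1.0, 1.0, 1.0]
    assert [out.nodes[n]["_y"] for n in ("r1", "r2", "r3")] == [-1.0, 0.0, 1.0]
    assert out.nodes["l1"]["_y"] == -0.5
    assert all(rec["_label"] for rec in out.nodes.values())


def test_bipartite_layout_single_nodes_center_at_zero():
    g = Graph(SCHEMA).add_node("l").add_node("r")
    out = al.bipartite_layout(g, {"l"}, {"r"})
    assert out.nodes["l"]["_y"] == 0.0 and out.nodes["r"]["_y"] == 0.0


def test_bipartite_layout_rejects_bad_partitions():
    g = Graph(SCHEMA).add_node("a").add_node("b")
    with pytest.raises(GraphError):
        al.bipartite_layout(g, {"a"}, set())  # non-covering
    with pytest.raises(GraphError):
        al.bipartite_layout(g, {"a", "b"}, {"b"})  # overlapping


def test_force_layout_deterministic_and_zero_iterations():
    g = cycle4()
    a = al.force_layout(g, iterations=30, rng_seed=9)
    b = al.force_layout(g, iterations=30, rng_seed=9)
    assert a == b
    init = al.force_layout(g, iterations=0, rng_seed=9)
    rng = np.random.default_rng(9)
    pos = rng.uniform(-1, 1, size=(4, 2))
    for i, name in enumerate(sorted(init.nodes)):
        assert init.nodes[name]["_x"] == pytest.approx(pos[i, 0])
    # z is never touched
    assert all(rec["_z"] == 0.0 for rec in a.nodes.values())


def test_force_layout_pulls_connected_nodes_closer():
    g = Graph(SCHEMA)
    g.add_link("a", "b")
    g.add_node("c")
    g.add_node("d")
    linked, unlinked = [], []
    for seed in range(20):
        out = al.force_layout(g, iterations=60, rng_seed=seed)

        def dist(u, v):
            return math.hypot(
                out.nodes[u]["_x"] - out.nodes[v]["_x"],
                out.nodes[u]["_y"] - out.nodes[v]["_y"],
            )

        linked.append(dist("a", "b"))
        unlinked.append(dist("c", "d"))
    assert np.mean(linked) < np.mean(unlinked)


@pytest.fixture
def expr_graph():
    g = Graph(SCHEMA)
    g.add_link("up1", "up2")
    g.add_link("down1", "down2")
    g.add_link("up1", "down1")
    g.add_link("up1", "unmapped")
    g.add_node("flat")
    return g


@pytest.fixture
def expr_table():
    cfg = GeneratorConfig(seed=3)
    return gen_expression_table(
        cfg, ["up1", "up2"], ["down1", "down2"],
        genes=["up1", "up2", "down1", "down2", "flat"],
    )


def test_overlay_expression_colors_by_log_ratio_sign(expr_graph, expr_table):
    out = al.overlay_expression(expr_graph, expr_table)
    color = lambda n: (out.nodes[n]["_r"], out.nodes[n]["_g"], out.nodes[n]["_b"])
    assert color("up1") == al.GREEN and color("up2") == al.GREEN
    assert color("down1") == al.RED and color("down2") == al.RED
    assert color("flat") == al.GRAY  # treatment == control
    assert color("unmapped") == al.GRAY  # absent from the table


def test_overlay_expression_radius_scales_with_fold_change(expr_graph, expr_table):
    out = al.overlay_expression(expr_graph, expr_table)
    row = expr_table.set_index("gene").loc["up1"]
    lr = math.log2(row["treatment"] / row["control"])
    assert out.nodes["up1"]["_radius"] == pytest.approx(1.0 + abs(lr))
    assert out.nodes["unmapped"]["_radius"] == 1.0


def test_overlay_expression_is_local_to_each_row(expr_graph, expr_table):
    shuffled = expr_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert al.overlay_expression(expr_graph, expr_table) == al.overlay_expression(
        expr_graph, shuffled
    )


def test_overlay_expression_input_validation(expr_graph, expr_table):
    import pandas as pd

    bad = expr_table.copy()
    bad.loc[0, "control"] = 0.0
    with pytest.raises(GraphError):
        al.overlay_expression(expr_graph, bad)
    dup = pd.concat([expr_table, expr_table.iloc[[0]]])
    with pytest.raises(GraphError):
        al.overlay_expression(expr_graph, dup)


def test_link_coloring_requires_endpoint_agreement(expr_graph, expr_table):
    out = al.color_links_by_expression(al.overlay_expression(expr_graph, expr_table))
    lcolor = lambda u, v: tuple(
        out.links[out.canonical(u, v)][c] for c in ("_r", "_g", "_b")
    )
    assert lcolor("up1", "up2") == al.GREEN
    assert lcolor("down1", "down2") == al.RED
    assert lcolor("up1", "down1") == al.GRAY  # disagreement
    assert lcolor("up1", "unmapped") == al.GRAY  # touches a gray node
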