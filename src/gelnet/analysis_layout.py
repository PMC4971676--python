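"""Network-analysis layouts: crown-plot, hub extraction, layering, bipartite
and force-directed placement, and expression overlay coloring.

All procedures are pure with respect to topology: they only write the
reserved visual attributes (positions, colors, radius, width, label) and
never touch node/link sets or user attributes.

A *hub* is a node whose degree in the analyzed graph meets a user-chosen
threshold; an *in-betweener* is a non-hub node adjacent to two or more hubs.
The crown-plot places all nodes on a unit circle in the x-y plane and lifts
each node to a height equal to its connectivity, which makes hubs stand out
of the crown; the three-layer view then separates ordinary genes, hubs, and
in-betweeners along z.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .graph_model import Graph, GraphError

__all__ = [
    "crown_plot",
    "extract_hub_subnet",
    "assign_layers",
    "bipartite_layout",
    "force_layout",
    "overlay_expression",
    "color_links_by_expression",
    "GREEN",
    "RED",
    "GRAY",
]

GREEN = (0.0, 1.0, 0.0)
RED = (1.0, 0.0, 0.0)
GRAY = (0.5, 0.5, 0.5)


def _set_color(rec: dict, rgb: tuple[float, float, float]) -> None:
    rec["_r"], rec["_g"], rec["_b"] = (float(c) for c in rgb)


def _node_color(rec: dict) -> tuple[float, float, float]:
    return (rec["_r"], rec["_g"], rec["_b"])


def crown_plot(g: Graph, hub_threshold: int, rng_seed: int = 0) -> Graph:
    """Circle layout with degree mapped to z; hubs enlarged and labeled.

    Nodes are spaced evenly on the unit circle in sorted-name order; ``_z``
    is the node degree; colors come from a seeded random generator so a given
    seed always yields the same picture.  Each link takes the color of its
    higher-z endpoint (color "bleeding" down the links), and nodes at or
    above *hub_threshold* get a doubled radius and a ``"name (degree)"``
    label.
    """
    if hub_threshold < 1:
        raise GraphError("hub_threshold must be >= 1")
    if not g.nodes:
        raise GraphError("crown_plot of an empty graph")
    out = g.copy()
    rng = np.random.default_rng(rng_seed)
    names = sorted(out.nodes)
    n = len(names)
    for i, name in enumerate(names):
        rec = out.nodes[name]
        angle = 2.0 * math.pi * i / n
        rec["_x"], rec["_y"] = math.cos(angle), math.sin(angle)
        deg = out.degree(name)
        rec["_z"] = float(deg)
        _set_color(rec, tuple(rng.random(3)))
        if deg >= hub_threshold:
            rec["_radius"] = rec["_radius"] * 2.0
            rec["_label"] = f"{name} ({deg})"
    for (a, b), rec in out.links.items():
        za, zb = out.nodes[a]["_z"], out.nodes[b]["_z"]
        top = a if (za, a) >= (zb, b) else b
        _set_color(rec, _node_color(out.nodes[top]))
    return out


def extract_hub_subnet(g: Graph, hub_threshold: int) -> Graph:
    """Links incident to at least one hub, plus all their endpoints."""
    if hub_threshold < 1:
        raise GraphError("hub_threshold must be >= 1")
    hubs = {n for n in g.nodes if g.degree(n) >= hub_threshold}
    out = Graph(g.schema)
    for key, rec in g.links.items():
        if key[0] in hubs or key[1] in hubs:
            for end in key:
                if end not in out.nodes:
                    out.nodes[end] = dict(g.nodes[end])
                    out._adj[end] = set()
            out.links[key] = dict(rec)
            out._adj[key[0]].add(key)
            out._adj[key[1]].add(key)
    return out


def assign_layers(sub: Graph, hubs: Iterable[str], spacing: float = 1.0) -> Graph:
    """Three-layer z assignment: ordinary nodes 0, hubs 1·s, in-betweeners 2·s.

    An in-betweener is a non-hub node adjacent (in *sub*) to two or more of
    the given hubs; hub status wins for nodes that are hubs themselves.
    """
    hubs = set(hubs)
    unknown = hubs - set(sub.nodes)
    if unknown:
        raise GraphError(f"hub name(s) not in graph: {sorted(unknown)}")
    out = sub.copy()
    for name, rec in out.nodes.items():
        if name in hubs:
            rec["_z"] = 1.0 * spacing
        elif len(out.neighbors(name) & hubs) >= 2:
            rec["_z"] = 2.0 * spacing
        else:
            rec["_z"] = 0.0
    return out


def bipartite_layout(g: Graph, left_set: Iterable[str], right_set: Iterable[str]) -> Graph:
    """Two columns at x = -1 and x = +1, evenly spaced in y by sorted name.

    The two sets must be disjoint and together cover the graph's nodes.
    Labels are set to the node names.
    """
    left, right = set(left_set), set(right_set)
    if left & right:
        raise GraphError(f"left and right sets overlap: {sorted(left & right)}")
    allnodes = set(g.nodes)
    if left | right != allnodes:
        missing = sorted(allnodes - (left | right)) + sorted((left | right) - allnodes)
        raise GraphError(f"left/right sets must cover the graph exactly; off by {missing}")
    out = g.copy()
    for column, x in ((left, -1.0), (right, 1.0)):
        members = sorted(column)
        m = len(members)
        for i, name in enumerate(members):
            rec = out.nodes[name]
            rec["_x"] = x
            rec["_y"] = i - (m - 1) / 2.0
            rec["_z"] = 0.0
            rec["_label"] = name
    return out


def force_layout(g: Graph, iterations: int = 50, rng_seed: int = 0) -> Graph:
    """Fruchterman–Reingold spring embedding in the x-y plane (z untouched).

    Starts from a seeded random placement, so a fixed seed is fully
    deterministic; 0 iterations returns the seeded initial placement.
    """
    if iterations < 0:
        raise GraphError("iterations must be >= 0")
    out = g.copy()
    names = sorted(out.nodes)
    n = len(names)
    if n == 0:
        return out
    index = {name: i for i, name in enumerate(names)}
    rng = np.random.default_rng(rng_seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    edges = np.array(
        [(index[a], index[b]) for a, b in out.links if a != b], dtype=int
    ).reshape(-1, 2)
    k = math.sqrt(4.0 / n)  # ideal spring length for a side-2 square
    t = 0.2
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion between all pairs
        disp = (delta / dist[..., None]) * (k * k / dist)[..., None]
        disp = disp.sum(axis=1)
        # attraction along links
        if len(edges):
            d = pos[edges[:, 0]] - pos[edges[:, 1]]
            dl = np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-9)
            f = d / dl * (dl * dl / k)
            np.add.at(disp, edges[:, 0], -f)
            np.add.at(disp, edges[:, 1], f)
        length = np.maximum(np.linalg.norm(disp, axis=-1, keepdims=True), 1e-9)
        pos += disp / length * np.minimum(length, t)
        t -= dt
    for name, i in index.items():
        out.nodes[name]["_x"] = float(pos[i, 0])
        out.nodes[name]["_y"] = float(pos[i, 1])
    return out


def overlay_expression(
    g: Graph,
    table: pd.DataFrame,
    min_abs_log2: float = 0.0,
) -> Graph:
    """Color genes by expression change relative to control.

    *table* has columns ``gene``, ``control``, ``treatment``.  A mapped gene
    turns green when log2(treatment/control) > 0, red when < 0, gray at
    exactly 0 (no stated fold-change cutoff; *min_abs_log2* optionally
    requires a minimum magnitude).  Genes absent from the table stay gray.
    Node radius grows linearly with |log2 ratio|.
    """
    required = {"gene", "control", "treatment"}
    if not required.issubset(table.columns):
        raise GraphError(f"expression table needs columns {sorted(required)}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise GraphError(f"duplicate gene rows in expression table: {dups}")
    if (table["control"] <= 0).any():
        raise GraphError("control values must be positive for ratio computation")
    ratios = dict(
        zip(table["gene"], np.log2(table["treatment"] / table["control"]))
    )
    out = g.copy()
    for name, rec in out.nodes.items():
        lr = ratios.get(name)
        if lr is None or abs(lr) <= min_abs_log2:
            _set_color(rec, GRAY)
            if lr is not None:
                rec["_radius"] = 1.0 + abs(float(lr))
            continue
        _set_color(rec, GREEN if lr > 0 else RED)
        rec["_radius"] = 1.0 + abs(float(lr))
    return out


def color_links_by_expression(g: Graph) -> Graph:
    """Green/red links only where both endpoints agree in sign, else gray.

    Apply after :func:`overlay_expression`; with both-endpoint agreement a
    whole pathway reads as up- or down-regulated at a glance.
    """
    out = g.copy()
    for (a, b), rec in out.links.items():
        ca, cb = _node_color(out.nodes[a]), _node_color(out.nodes[b])
        if ca == cb and ca in (GREEN, RED):
            _set_color(rec, ca)
        else:
            _set_color(rec, GRAY)
    return out
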