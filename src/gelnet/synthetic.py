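"""Deterministic generators for every input class used in tests and demos.

The generators emulate the *interfaces* of the real data sources — a dense
weighted gene-correlation network (WGCNA-like), a pathway network of gene
chains, a two-condition expression table, and toy KGML pathway files — with
planted, exactly recoverable structure.  They do not imitate the internals
of WGCNA or KEGG; they produce graphs with the same shape, attributes and
statistical character so that every analysis in this package can be
exercised and checked without any download.

Planted structure and recovery margins
--------------------------------------
The correlation-like network plants hubs (high-degree nodes), in-betweeners
(non-hubs wired to exactly two hubs) and a set of links shared with the
pathway-like network.  Background links are sampled only among non-hub
genes, hub spoke pools are disjoint, and background sampling skips pathway
chain pairs.  These margins make the planted structure exactly recoverable:
hub extraction at the planted threshold finds precisely the planted hubs,
the graph intersection of the two networks equals the planted shared links,
and the layer assignment puts exactly the planted in-betweeners on the top
layer.  Everything is a pure function of the configuration (seed included).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .graph_model import (
    AttributeSpec,
    Graph,
    GraphError,
    GraphSchema,
    LinkType,
    NodeType,
    simple_schema,
)

__all__ = [
    "GeneratorConfig",
    "PlantedNetworks",
    "gen_worked_example_pair",
    "gen_corr_path_pair",
    "gen_corr_like",
    "gen_path_like",
    "gen_expression_table",
    "gen_toy_kgml",
    "write_stress_tabular",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the planted-network pair.

    Defaults give a desk-scale analysis: 500 genes, ~1.2k background
    correlation links (mean degree ~5, far below the hub degree so planted
    hubs are unambiguous), 5 hubs of degree 25, 3 in-betweeners, 10 pathway
    chains of 12 genes, and 40 links shared between the two networks.
    """

    seed: int = 42
    n_genes: int = 500
    corr_density: float = 0.01
    n_planted_hubs: int = 5
    hub_degree: int = 25
    n_inbetweeners: int = 3
    pathway_count: int = 10
    pathway_size: int = 12
    n_shared_links: int = 40

    def __post_init__(self):
        if min(self.n_genes, self.n_planted_hubs, self.hub_degree,
               self.pathway_count, self.pathway_size) <= 0:
            raise GraphError("all generator counts must be positive")
        if not 0.0 < self.corr_density <= 1.0:
            raise GraphError("corr_density must be in (0, 1]")
        if self.hub_degree >= self.n_genes:
            raise GraphError("hub_degree must be below n_genes")


@dataclass(frozen=True)
class PlantedNetworks:
    """A correlation-like / pathway-like pair with its planted ground truth."""

    corr: Graph
    path: Graph
    shared_links: frozenset
    hubs: tuple
    inbetweeners: tuple


CORR_SCHEMA = simple_schema(
    link_attrs=[("weight", "double")], node_name="gene_nt", link_name="corr_lt"
)
PATH_SCHEMA = simple_schema(node_name="gene_nt", link_name="path_lt")


def gen_worked_example_pair() -> tuple[Graph, Graph]:
    """The worked two-graph example used throughout the attribute-merge rules.

    A has node attributes (id, count) and nodes a,b,c,d with links
    (a,b), (b,c) and (b,d, weight 0.4); B has node attributes (id, tag) and
    nodes b,d,e with links (b,d, weight 0.3) and (d,e).  Both link types
    declare ``weight: double`` with default 0.
    """
    schema_a = simple_schema(
        node_attrs=[("id", "string"), ("count", "int")],
        link_attrs=[("weight", "double")],
        node_name="ntA", link_name="ltA",
    )
    schema_b = simple_schema(
        node_attrs=[("id", "string"), ("tag", "string")],
        link_attrs=[("weight", "double")],
        node_name="ntB", link_name="ltB",
    )
    a = Graph(schema_a)
    for n in "abcd":
        a.add_node(n)
    a.add_link("a", "b")
    a.add_link("b", "c")
    a.add_link("b", "d", {"weight": 0.4})
    b = Graph(schema_b)
    for n in "bde":
        b.add_node(n)
    b.add_link("b", "d", {"weight": 0.3})
    b.add_link("d", "e")
    return a, b


def _gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def gen_corr_path_pair(cfg: GeneratorConfig = GeneratorConfig()) -> PlantedNetworks:
    """Generate the correlation-like and pathway-like networks together.

    The pathway network is ``pathway_count`` disjoint chains of
    ``pathway_size`` genes (no link attributes); ``n_shared_links`` of its
    chain links are also planted in the correlation network, whose remaining
    links are hub spokes, in-betweener wires and uniform background noise
    with weights ~ Uniform(-1, 1).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    order = [genes[i] for i in rng.permutation(cfg.n_genes)]
    hubs = tuple(order[: cfg.n_planted_hubs])
    k = cfg.n_planted_hubs
    inbetweeners = tuple(order[k : k + cfg.n_inbetweeners])
    rest = order[k + cfg.n_inbetweeners :]

    n_chain_genes = cfg.pathway_count * cfg.pathway_size
    if n_chain_genes > len(rest):
        raise GraphError("pathway chains need more genes than are available")
    max_shared = cfg.pathway_count * (cfg.pathway_size - 1)
    if cfg.n_shared_links > max_shared:
        raise GraphError(
            f"cannot plant {cfg.n_shared_links} shared links in "
            f"{max_shared} chain links"
        )
    if cfg.n_planted_hubs * cfg.hub_degree > len(rest):
        raise GraphError("hub spoke pools need more genes than are available")

    # pathway-like network: disjoint chains over a slice of the non-hub genes
    path = Graph(PATH_SCHEMA)
    chain_genes = rest[:n_chain_genes]
    chain_links: list[tuple[str, str]] = []
    for c in range(cfg.pathway_count):
        chain = chain_genes[c * cfg.pathway_size : (c + 1) * cfg.pathway_size]
        for gene in chain:
            path.add_node(gene)
        for u, v in zip(chain, chain[1:]):
            path.add_link(u, v)
            chain_links.append(path.canonical(u, v))

    pick = rng.choice(len(chain_links), size=cfg.n_shared_links, replace=False)
    shared = frozenset(chain_links[i] for i in sorted(pick))
    chain_set = set(chain_links)

    corr = Graph(CORR_SCHEMA)
    for gene in genes:
        corr.add_node(gene)
    # disjoint spoke pools keep every spoke partner adjacent to exactly one hub
    for i, hub in enumerate(hubs):
        pool = rest[i * cfg.hub_degree : (i + 1) * cfg.hub_degree]
        for partner in pool:
            corr.add_link(hub, partner, {"weight": float(rng.uniform(0.5, 1.0))})
    # each in-betweener wires to two distinct hubs
    for j, node in enumerate(inbetweeners):
        for hub in (hubs[j % k], hubs[(j + 1) % k]):
            corr.add_link(node, hub, {"weight": float(rng.uniform(0.5, 1.0))})
    for u, v in sorted(shared):
        corr.add_link(u, v, {"weight": float(rng.uniform(-1.0, 1.0))})
    # uniform background among non-hub genes, skipping chain pairs so the
    # cross-network link intersection stays exactly the planted set
    non_hub = [g for g in genes if g not in hubs]
    m = len(non_hub)
    n_background = int(round(cfg.corr_density * m * (m - 1) / 2))
    attempts = 0
    placed = 0
    while placed < n_background and attempts < 50 * n_background + 100:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        key = corr.canonical(non_hub[i], non_hub[j])
        if key in corr.links or key in chain_set:
            continue
        corr.add_link(key[0], key[1], {"weight": float(rng.uniform(-1.0, 1.0))})
        placed += 1

    return PlantedNetworks(corr, path, shared, hubs, inbetweeners)


def gen_corr_like(cfg: GeneratorConfig = GeneratorConfig()) -> Graph:
    """The correlation-like network of :func:`gen_corr_path_pair`."""
    return gen_corr_path_pair(cfg).corr


def gen_path_like(cfg: GeneratorConfig = GeneratorConfig()) -> Graph:
    """The pathway-like network of :func:`gen_corr_path_pair`."""
    return gen_corr_path_pair(cfg).path


def gen_expression_table(
    cfg: GeneratorConfig,
    up_set: Iterable[str],
    down_set: Iterable[str],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Two-condition expression table (columns gene, control, treatment).

    Control values are LogNormal(5, 1); treatment = control · 2^delta with
    delta ~ +Uniform(0.5, 3) for *up_set*, -Uniform(0.5, 3) for *down_set*
    and 0 otherwise.  *genes* defaults to the configuration's gene names.
    """
    up, down = set(up_set), set(down_set)
    overlap = up & down
    if overlap:
        raise GraphError(f"up and down sets overlap: {sorted(overlap)}")
    if genes is None:
        genes = _gene_names(cfg.n_genes)
    genes = list(genes)
    rng = np.random.default_rng(cfg.seed + 1)
    control = rng.lognormal(mean=5.0, sigma=1.0, size=len(genes))
    delta = np.zeros(len(genes))
    for i, gene in enumerate(genes):
        if gene in up:
            delta[i] = rng.uniform(0.5, 3.0)
        elif gene in down:
            delta[i] = -rng.uniform(0.5, 3.0)
    return pd.DataFrame(
        {"gene": genes, "control": control, "treatment": control * 2.0 ** delta}
    )


def gen_toy_kgml(n_genes: int, n_compounds: int, seed: int = 0,
                 pathway_name: str = "path:toy00010") -> str:
    """A small, well-formed KGML document (returned as XML text).

    Gene entries sit on a grid and are chained by relations; each compound is
    attached to a gene through a reaction substrate edge.  Deterministic for
    a fixed argument tuple.
    """
    if n_genes < 0 or n_compounds < 0:
        raise GraphError("entry counts must be >= 0")
    rng = np.random.default_rng(seed)
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="{pathway_name}" org="toy" number="00010" '
        'title="Synthetic toy pathway">',
    ]
    x0 = int(rng.integers(0, 10))  # seed-determined grid origin
    eid = 0
    gene_ids, compound_ids = [], []
    for i in range(n_genes):
        eid += 1
        gene_ids.append(eid)
        reaction = f' reaction="rn:R{i + 1:05d}"' if i < n_compounds else ""
        lines.append(
            f'  <entry id="{eid}" name="toy:g{i + 1}" type="gene"{reaction}>'
        )
        lines.append(
            f'    <graphics name="g{i + 1}" x="{x0 + 100 * (i + 1)}" y="100" '
            'width="46" height="17" type="rectangle"/>'
        )
        lines.append("  </entry>")
    for j in range(n_compounds):
        eid += 1
        compound_ids.append(eid)
        lines.append(f'  <entry id="{eid}" name="cpd:C{j + 1:05d}" type="compound">')
        lines.append(
            f'    <graphics name="C{j + 1:05d}" x="{x0 + 100 * (j + 1)}" y="200" '
            'width="8" height="8" type="circle"/>'
        )
        lines.append("  </entry>")
    for a, b in zip(gene_ids, gene_ids[1:]):
        lines.append(f'  <relation entry1="{a}" entry2="{b}" type="ECrel">')
        lines.append('    <subtype name="compound" value="0"/>')
        lines.append("  </relation>")
    for j, cid in enumerate(compound_ids):
        if not gene_ids:
            break
        gid = gene_ids[j % len(gene_ids)]
        lines.append(
            f'  <reaction id="{gid}" name="rn:R{j + 1:05d}" type="irreversible">'
        )
        lines.append(f'    <substrate id="{cid}" name="cpd:C{j + 1:05d}"/>')
        lines.append("  </reaction>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def write_stress_tabular(path: str, n_genes: int, n_links: int, seed: int = 0) -> None:
    """Stream a large random weighted edge list in the tabular dialect.

    Used for performance smoke tests (~1M links) without building the graph
    in memory first.  Duplicate endpoint pairs may occur; the importer
    de-duplicates them last-wins, as for any tabular input.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        for i in range(1, n_genes + 1):
            writer.writerow([f"g{i:06d}"])
        writer.writerow(["-"])
        chunk = 100_000
        written = 0
        while written < n_links:
            size = min(chunk, n_links - written)
            pairs = rng.integers(1, n_genes + 1, size=(size, 2))
            weights = rng.uniform(-1.0, 1.0, size=size)
            for (u, v), w in zip(pairs, weights):
                if u == v:
                    continue
                writer.writerow([f"g{u:06d}", f"g{v:06d}", f"{w:.6f}"])
            written += size
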