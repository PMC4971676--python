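"""KGML (KEGG Markup Language) pathway parsing and layered merging.

A KGML file describes one pathway diagram: ``entry`` elements (pathway maps,
genes/enzymes, compounds, orthologs) with 2D drawing coordinates, plus
``relation`` and ``reaction`` elements connecting them.  Parsing yields a
typed graph that preserves the KEGG coordinates and colors entries by class:
red for pathway maps, green for genes/enzymes, blue for compounds, yellow
for orthologs (gray for anything else).  KGML's y axis grows downward, so y
is negated on import and rendered layouts match the KEGG website drawing.

Relations and substrate/product edges are loaded as undirected links so that
pathway graphs compose directly with undirected correlation/GO/PPI networks.
Multiple pathways can be merged onto stacked z layers.
"""

from __future__ import annotations

import os
import urllib.request
import warnings
from typing import Iterable

from lxml import etree

from .algebra import dotted_add
from .graph_model import (
    AttributeSpec,
    Graph,
    GraphError,
    GraphSchema,
    GraphWarning,
    LinkType,
    NodeType,
)

__all__ = [
    "PATHWAY_SCHEMA",
    "CLASS_COLORS",
    "parse_kgml",
    "merge_layered",
    "fetch_pathway",
]

PATHWAY_SCHEMA = GraphSchema(
    NodeType(
        "kegg_node",
        (
            AttributeSpec("name", "string"),
            AttributeSpec("names", "string"),  # all KEGG ids of the entry
            AttributeSpec("eclass", "string"),
        ),
    ),
    LinkType("kegg_link", False, ()),
)

_ECLASSES = {"map", "compound", "gene", "ortholog", "enzyme"}

#: entry class -> node RGB, per the pathway-diagram convention
CLASS_COLORS = {
    "map": (1.0, 0.0, 0.0),
    "gene": (0.0, 1.0, 0.0),
    "enzyme": (0.0, 1.0, 0.0),
    "compound": (0.0, 0.0, 1.0),
    "ortholog": (1.0, 1.0, 0.0),
    "other": (0.5, 0.5, 0.5),
}

_GENE_CLASSES = {"gene", "enzyme", "ortholog"}


def parse_kgml(path: str, gene_only: bool = False) -> Graph:
    """Parse one KGML file into a pathway graph.

    One node per entry, named by the entry's first KEGG id; entries sharing
    an id collapse into a single node and their links are re-targeted.
    Links come from ``relation`` elements and from reaction substrate/product
    edges.  With ``gene_only`` only gene/enzyme/ortholog entries (and links
    among them) are kept.
    """
    try:
        root = etree.parse(path).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise GraphError(f"cannot parse KGML file {path!r}: {exc}") from None
    g = Graph(PATHWAY_SCHEMA)
    entry_name: dict[str, str] = {}  # KGML entry id -> node name
    for entry in root.iter("entry"):
        eid = entry.get("id")
        ids = (entry.get("name") or "").split()
        if not ids:
            ids = [f"entry{eid}"]
        name = ids[0]
        etype = entry.get("type") or "other"
        eclass = etype if etype in _ECLASSES else "other"
        if gene_only and eclass not in _GENE_CLASSES:
            continue
        entry_name[eid] = name
        if name in g.nodes:  # merge duplicate entries by name
            continue
        graphics = entry.find("graphics")
        if graphics is None or graphics.get("x") is None or graphics.get("y") is None:
            warnings.warn(
                f"entry {eid} ({name}) has no graphics coordinates; placed at origin",
                GraphWarning,
                stacklevel=2,
            )
            x = y = 0.0
        else:
            x, y = float(graphics.get("x")), float(graphics.get("y"))
        values = {"names": " ".join(ids), "eclass": eclass}
        g.add_node(name, values)
        rec = g.nodes[name]
        rec["_x"], rec["_y"], rec["_z"] = x, -y, 0.0
        rec["_r"], rec["_g"], rec["_b"] = CLASS_COLORS[eclass]
    for rel in root.iter("relation"):
        a, b = entry_name.get(rel.get("entry1")), entry_name.get(rel.get("entry2"))
        if a is None or b is None:
            continue
        if g.canonical(a, b) not in g.links:
            g.add_link(a, b)
    for reaction in root.iter("reaction"):
        enzyme = entry_name.get(reaction.get("id"))
        if enzyme is None:
            continue
        for side in ("substrate", "product"):
            for el in reaction.iter(side):
                other = entry_name.get(el.get("id"))
                if other is not None and g.canonical(enzyme, other) not in g.links:
                    g.add_link(enzyme, other)
    g.validate()
    return g


def merge_layered(pathways: Iterable[Graph], spacing: float = 1.0) -> Graph:
    """Merge pathways with pathway i lifted to z = i·spacing.

    The fold uses the dotted addition; a node occurring in several pathways
    keeps the z of the first pathway that contains it.
    """
    pathways = list(pathways)
    if not pathways:
        raise GraphError("merge_layered needs at least one pathway")
    first_layer: dict[str, int] = {}
    for i, p in enumerate(pathways):
        for name in p.nodes:
            first_layer.setdefault(name, i)
    merged = pathways[0]
    for p in pathways[1:]:
        merged = dotted_add(merged, p)
    if merged is pathways[0]:
        merged = merged.copy()
    for name, rec in merged.nodes.items():
        rec["_z"] = first_layer[name] * spacing
    return merged


KEGG_KGML_URL = "https://rest.kegg.jp/get/{pathway}/kgml"


def fetch_pathway(organism: str, pathway_id: str, cache_dir: str = "kegg_cache") -> str:
    """Download a pathway's KGML into *cache_dir* (cache hit skips the network).

    Optional online feature; returns the path of the cached XML file.  Parse
    it with :func:`parse_kgml`.
    """
    if not pathway_id.startswith(organism):
        pathway_id = organism + pathway_id
    os.makedirs(cache_dir, exist_ok=True)
    target = os.path.join(cache_dir, f"{pathway_id}.xml")
    if os.path.exists(target):
        return target
    url = KEGG_KGML_URL.format(pathway=pathway_id)
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            data = resp.read()
    except OSError as exc:
        raise GraphError(f"cannot fetch pathway {pathway_id!r}: {exc}") from None
    with open(target, "wb") as fh:
        fh.write(data)
    return target
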