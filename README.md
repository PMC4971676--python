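# gelnet

Typed attribute graphs, a formally specified eight-operator graph algebra,
a small graph-exploration script language (a documented Gel dialect), and
the network-analysis procedures built on them: crown-plots, hub/in-betweener
extraction, bipartite and force-directed layouts, KEGG KGML pathway
parsing with layered 3D merging, and microarray-expression overlays.

## The problem

Systems-biology questions routinely cross data types: a weighted
gene-coexpression (WGCNA-style) network, a KEGG pathway network, a GO
co-annotation network and a protein–protein interaction network all describe
the same genes but carry different link attributes. Comparing or integrating
them means set arithmetic over graphs *plus* a policy for what happens to
conflicting attributes. `gelnet` makes both explicit.

A graph is `G = {V, E}` with `E ⊆ {(v_i, v_j) | v_i, v_j ∈ V}`. Nodes and
links carry typed attributes (`string`, `int`, `float`, `double`) declared
with defaults; the first node attribute is always the string node name, and
a link is identified purely by its endpoint pair. Eight binary operators
combine graphs; dotted forms are node-centric, non-dotted forms keep the
left node set:

| operator | result |
|---|---|
| `A .+ B` | `{V_A ∪ V_B, E_A ∪ E_B}` |
| `A + B`  | `{V_A, E_A ∪ {(u,v) ∈ E_B : u,v ∈ V_A}}` |
| `A .- B` | `{V_A ∖ V_B, links of E_A ∖ E_B with both endpoints surviving}` |
| `A - B`  | `{V_A, E_A ∖ E_B}` |
| `A .& B` | `{V_A ∩ V_B, E_A ∩ E_B}` |
| `A & B`  | `{V_A, E_A ∩ E_B}` |
| `A * B`  | union plus all cross links `u ∈ V_A, v ∈ V_B, u ≠ v` |
| `A ** B` | as `*` without the `u ≠ v` restriction (self-loops on shared nodes) |

Attribute conflicts resolve by **left precedence with a default exception**:
the left value wins unless it equals its declared default and the right
operand declares a matching attribute, in which case the right value is
copied. Combining graphs of different types uses **attribute promotion**:
declare a type with the union of the attributes, assign one graph into it,
then add the other — both attribute sets survive.

Every graph also carries reserved visual attributes (`_x,_y,_z`, `_r,_g,_b`,
`_radius`, `_label` on nodes; `_r,_g,_b`, `_width` on links), so any
analysis result can be turned into a picture by mapping information
attributes onto them (`foreach G nodes set _z := degree();`).

## Worked example

```python
from gelnet.gel_dsl import run_script

env = run_script("""
nodetype gene(id: string, count: int);
linktype corr[weight: double];

graph A: gene, corr = {
  a(); b(); c(); d();
  a - b []; b - c []; b - d [weight=0.4];
};
graph B: gene, corr = {
  b(); d(); e();
  b - d [weight=0.3]; d - e [];
};

U = A .+ B;
I = A .& B;
foreach U nodes set _z := degree();
foreach U links tally count, sum(weight);
list;
""")
print("w(b,d) in U:", env.graphs["U"].links[("b", "d")]["weight"])
print("I:", sorted(env.graphs["I"].nodes), sorted(env.graphs["I"].links))
```

prints

```
4  0.4
A: 4 nodes, 3 links | node attrs: id, count | link attrs: weight
B: 3 nodes, 2 links | node attrs: id, count | link attrs: weight
U: 5 nodes, 4 links | node attrs: id, count | link attrs: weight
I: 2 nodes, 1 links | node attrs: id, count | link attrs: weight
w(b,d) in U: 0.4
I: ['b', 'd'] [('b', 'd')]
```

The tally line (`4  0.4`) counts U's links and sums their weights. The
union `U` keeps weight 0.4 on link (b,d) — the left operand's non-default
value wins over B's 0.3 — and the intersection `I` contains exactly the
shared node pair {b, d} and their shared link.

A typical analysis pipeline on synthetic data, from the shell:

```sh
gelnet synth corr --seed 42 --out corr.csv
gelnet import --schema docs/examples/corr_schema.gel --in corr.csv --out corr.gel
gelnet crown-plot --in corr.gel --out crown.gel --threshold 20 --seed 1
gelnet hubs --in corr.gel --out hubs.gel --threshold 20
gelnet render --in crown.gel --out crown.png
```

`gelnet repl` starts an interactive console (`help;` lists every command and
operator), `gelnet run script.gel` replays a saved analysis, and graphs
saved with `save G "g.gel";` are executable scripts that rebuild the graph —
visual attributes included — when run again.

## Layout and further docs

- `src/gelnet/graph_model.py` — typed schemas, records, the Graph container
- `src/gelnet/algebra.py` — the eight operators and the merge policy
- `src/gelnet/graph_io.py` — tabular (CSV/TSV) import/export, script save/load
- `src/gelnet/query.py` — select / foreach over attributes and degree
- `src/gelnet/gel_dsl.py` — lexer, parser, evaluator, REPL
- `src/gelnet/analysis_layout.py` — crown-plot, hubs, layers, bipartite,
  force-directed, expression overlay
- `src/gelnet/kegg_kgml.py` — KGML parsing, layered merge, optional fetch
- `src/gelnet/synthetic.py` — deterministic generators for all test inputs

`docs/methods.md` describes the models, parameters and design choices;
`docs/gel_grammar.md` is the full grammar of the dialect.
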