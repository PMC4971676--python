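# Methods

## The graph model

A graph is a pair of typed tables: nodes keyed by name, links keyed by
endpoint pair. Node and link types are ordered lists of
`(name, primitive, default)` attribute declarations over the four
primitives `string`, `int`, `float`, `double`. `int` is a 64-bit signed
integer; `float` and `double` are both stored as double-precision reals but
keep distinct declared types for schema matching, since the declarations
distinguish the names even where the arithmetic does not. The first node
attribute is always a string holding the node name.

Graphs are **simple**: at most one link per canonical endpoint pair, with
duplicates overwriting last-wins under a warning. Link identity is the
endpoint pair alone — attribute values never participate in set membership.
For undirected link types the stored pair is lexicographically sorted, so
(b,d) and (d,b) are the same link. Self-loops are representable (the `**`
join creates them) and count 1 toward degree; this convention keeps
degree-derived layouts monotone in the number of incident links. Node-name
comparison is exact, case-sensitive and byte-wise, because gene symbols are
case-significant.

The closure invariant — both endpoints of every link exist as nodes — holds
after every operation; `add_link` auto-creates missing endpoints with
default attributes (an imported link list may mention nodes absent from the
node block), and a validator re-checks the invariant in tests.

Reserved visual attributes are appended to every declared type:
`_x,_y,_z` (unitless scene coordinates), `_r,_g,_b` (color components in
[0,1], default 0.5), `_radius` (default 1.0), `_label` for nodes, and
`_r,_g,_b`, `_width` (default 1.0) for links. The underscore prefix is
reserved so user attributes can never collide.

## The algebra and the merge policy

The eight operators implement plain set arithmetic on node-name sets and
endpoint-pair sets (see the README table). Design points that the equations
alone do not fix:

- The result schema is always the **left** operand's; right-operand records
  are coerced to it by attribute promotion (matched by name *and*
  primitive; a shared name with a different primitive is an error, never a
  silent cast). Preserving both operands' attributes requires the explicit
  promotion idiom: assign both into a graph declared with the union type.
- Conflicts resolve per **attribute**, not per record: the left value wins
  unless it equals its declared default and the right record declares a
  matching attribute, in which case the right value is copied. The
  per-attribute reading lets one record mix inherited and overridden
  fields, which is what makes default-filled promotions useful.
- Cross links created by `*`/`**` take all-default attributes and never
  overwrite an existing member of the union.
- Directed and undirected graphs cannot be combined; there is no principled
  coercion, so the operators refuse rather than guess.
- Operators never mutate operands; the DSL's compound assignments rebind
  the left name to a fresh result.
- The node set of the dotted intersection is `V_A ∩ V_B` (one published
  rendering of the equation repeats `V_A`; the intersection reading is the
  only one consistent with the `&` variant and with the worked examples).

Every operator is checked against an independent brute-force set-arithmetic
oracle over hundreds of random graph pairs, plus the inverse-graph identity
`G * G − G` = complement of `G`.

## Tabular and script I/O

The tabular dialect has no header row; columns follow declared attribute
order (node name first; link source and target first), a single hyphen line
separates the node block from the link block, and short rows fill trailing
attributes with defaults. Reals render in their shortest round-tripping
decimal form, exports are sorted (byte-stable across runs), and the comma
dialect uses standard CSV quoting while the tab dialect rejects embedded
tabs. A header row fails typed parsing loudly, which is the desired
behavior. Visual attributes are omitted unless requested, since tabular
export targets other programs; full visual state travels through script
serialization instead: `save_script` writes type declarations plus a graph
literal whose evaluation rebuilds the graph exactly.

## select / foreach

Node selection is an induced subgraph (a link survives only if both
endpoints were selected); link selection keeps each matching link plus its
endpoints. Both semantics are needed in practice: pulling hub links into a
sub-network must keep their endpoints, while selecting a gene set must not
leave dangling links. `foreach` updates evaluate all right-hand sides
against a snapshot of pre-update values, making results independent of
iteration order. Division by zero is an evaluation error, not a NaN.
`min`/`max` over an empty selection is an error; `count`/`sum` are 0.

## Analysis procedures

- **Crown-plot**: nodes evenly spaced on the unit circle in sorted-name
  order, `_z` = degree, node colors from a seeded generator (the seed is a
  parameter so figures are reproducible), each link flat-colored by its
  higher-z endpoint (a gradient would be a rendering concern), and nodes at
  or above the hub threshold get doubled radius and a `"name (degree)"`
  label.
- **Hubs and layers**: a hub is a node with degree ≥ a user-chosen
  threshold in the analyzed graph; no default is provided because the right
  threshold is data-dependent and choosing one silently would hide that
  decision. The hub sub-network is every link incident to a hub plus
  endpoints. Layering puts ordinary nodes at z = 0, hubs at z = s, and
  in-betweeners — non-hubs adjacent to ≥ 2 hubs; hub status wins — at
  z = 2s (spacing s defaults to 1).
- **Bipartite layout**: left column at x = −1, right at x = +1, members
  evenly spaced and centered in y by sorted name, labels set to names.
- **Force-directed layout**: a Fruchterman–Reingold spring embedding in the
  x-y plane with linear cooling, from a seeded uniform start; fixed seed ⇒
  identical coordinates, 0 iterations ⇒ the seeded initial placement. z is
  never touched so layered views survive flattening.
- **Expression overlay**: up/down is the sign of log2(treatment/control);
  exactly 0 and unmapped genes are gray (0.5, 0.5, 0.5). No fold-change
  cutoff is imposed; an optional minimum |log2 ratio| (default 0) is
  available. Node radius is 1 + |log2 ratio| — linear, the simplest
  monotone choice. Links turn green/red only when **both** endpoints agree
  in sign, the conservative reading that makes a whole pathway legible as
  up- or down-regulated; any link touching a gray node is gray. Control
  values must be positive and duplicate gene rows are an error.

## KGML parsing

One node per KGML entry, named by the entry's first KEGG id (all ids kept
in a `names` attribute); entries sharing an id collapse and links are
re-targeted. Links come from `relation` elements and reaction
substrate/product edges, loaded **undirected** so pathway graphs compose
with undirected correlation/GO/PPI networks (no analysis here uses relation
direction). Entry classes color as: map red, gene/enzyme green, compound
blue, ortholog yellow, anything else gray. KGML's y axis grows downward, so
y is negated on import and renderings match the source drawing. Missing
graphics coordinates place the node at the origin under a warning.
`merge_layered` folds pathways with the dotted addition and then pins each
node's `_z` to (index of its first containing pathway) × spacing; pinning
after the fold is required because a first-pathway z of 0 equals the
declared default and would otherwise be overridden by the merge policy's
default exception. Compounds are loaded as full link endpoints; a
`gene_only` flag projects them away where a gene-gene view is wanted. The
optional online fetch caches raw KGML and never retries silently; all
tests use locally generated fixtures.

## Synthetic data

The generators define the study conditions for every test; defaults were
chosen once as a realistic desk-scale analysis:

- 500 genes; background correlation density 0.01 (~1.2k background links,
  mean degree ≈ 5) so that planted hubs of degree 25 are unambiguous at an
  extraction threshold of 20 — the background degree distribution's tail
  stays far below the threshold;
- 5 hubs (degree 25), 3 in-betweeners, 10 pathway chains of 12 genes, 40
  shared links planted in both networks;
- expression controls are LogNormal(5, 1) with fold changes of
  2^±Uniform(0.5, 3) for perturbed genes.

Recovery is exact **by construction**: hub spoke pools are disjoint (no
accidental double-hub neighbors), background links avoid hub endpoints, and
background sampling skips non-planted chain pairs so the cross-network link
intersection equals the planted set. The generator emulates a WGCNA-style
artifact's *interface* — a weighted gene graph — not WGCNA's internals
(soft-thresholding, correlation estimation), and the pathway generator
produces chains, not real KEGG topologies. Passing tests therefore
demonstrate the correctness of the algebra, queries and analyses on graphs
of realistic shape; they say nothing about biological conclusions drawn
from any particular real data set. A separate stress generator streams
~10^6-link edge lists for import smoke tests.

## Numerical and degenerate-input choices

- Real attribute equality (for the merge default exception and for
  last-wins warnings) is exact floating-point comparison; defaults are
  copied verbatim at declaration, so a value equals its default only if it
  was never overwritten or was set back bit-exactly.
- Crown-plot placement uses exact trigonometry; the circle-radius test
  tolerance is 1e-9.
- Empty graphs: valid operands everywhere in the algebra and I/O; crown-plot
  refuses them (there is no circle of zero nodes); `merge_layered` requires
  at least one pathway.
- Link-color tie-break in the crown plot: equal-z endpoints resolve by name
  order, keeping output deterministic.

## Known limitations

Interactive 3D rendering, GPU acceleration and camera controls are out of
scope; `gelnet render` produces static orthographic projections of the
stored visual attributes. The DSL has no user-defined functions or control
flow beyond `foreach`. Graphs live in memory; there is no streaming or
on-disk backend, and multigraphs/hypergraphs are non-goals. Live GO/PPI
retrieval is not implemented; those networks are emulated synthetically.
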