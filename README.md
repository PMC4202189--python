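# pathkernel

Shared-subgraph discovery across biological pathway networks through a
bipartite edge–pathway data model.

## The problem

Collections of curated pathways (metabolic maps, signaling cascades,
interaction modules) frequently contain the same gene–gene relationships:
nine purine-metabolism pathways may all carry one core interaction, two
databases may describe the same signaling module with different extra
context. Classic gene-set tools ask *which genes* are shared; this
toolkit asks *which wiring* is shared, and organizes the answer
hierarchically.

The model:

1. **Decompose.** Each pathway graph is reduced to discrete gene–gene
   edges. Non-gene entities (metabolites, complexes, reaction nodes) are
   contracted away: two genes become an edge when they are directly
   connected or joined by an uninterrupted path whose internal nodes are
   all non-gene. Every distinct gene pair in the collection receives one
   unique integer edge id.
2. **Cross-tabulate.** The membership relation *edge e occurs in pathway
   p* is a bipartite graph between edge ids and pathway ids.
3. **Enumerate.** All **maximal bicliques** (E, P) of that bipartite
   graph are listed: every edge in E occurs in every pathway of P, and
   neither side can be extended. Each biclique is a subgraph shared
   *exactly* by a group of pathways.
4. **Arrange.** Bicliques are partially ordered by pathway-set
   containment (equivalently, reverse edge-set containment). The Hasse
   diagram of that order is a hierarchy whose top node is the kernel
   shared by the most pathways; descending it trades pathway breadth for
   edge detail.
5. **Summarize and color.** Each biclique's edge set is materialized as a
   gene graph and summarized by its largest connected component (LCC,
   computed by breadth-first search). The root graph is first augmented
   with the edges of hierarchy nodes up to two levels below it. Genes are
   colored by the highest (minimum-level) hierarchy node whose LCC
   contains them.

A bundled synthetic generator plants nested shared kernels plus
pathway-private noise, so the whole pipeline is testable end to end with
analytically known ground truth — no downloads required.

## Worked example

Generate an eight-pathway collection with four planted kernels, then run
the three analysis stages:

```sh
pathkernel simulate  --out sim --seed 7
pathkernel decompose --manifest sim/manifest.tsv --out dec
pathkernel bicliques --indir dec --out bic
pathkernel hierarchy --bicliques bic/bicliques.json \
                     --catalog dec/catalog.json --out hier
```

`dec/report_decompose.json` records the collection size — 8 pathways, 50
genes, 78 pathway-edge memberships over 52 unique edges (each shared
kernel edge is stored once but belongs to several pathways):

```json
{
  "n_edges_unique": 52,
  "n_edges_with_multiplicity": 78,
  "n_genes": 50,
  "n_pathways_input": 8,
  "n_pathways_kept": 8
}
```

`bic/bicliques.json` then holds exactly the four planted bicliques, from
the broadest kernel to the most refined:

```
6 pathways, 2 edges: P00 P01 P02 P03 P04 P05
3 pathways, 5 edges: P00 P01 P02
3 pathways, 5 edges: P03 P04 P05
2 pathways, 9 edges: P00 P01
```

and `hier/hierarchy.dot` arranges them with the most widely shared kernel
at the top, splitting into two three-pathway refinements, one of which
specializes further to a two-pathway subgraph:

```
n0 (6 pathways / 2 edges)
├── n1 (3 pathways / 5 edges) ── n3 (2 pathways / 9 edges)
└── n2 (3 pathways / 5 edges)
```

The five-edge sets each contain the two root edges: moving down the
hierarchy, pathway groups shrink while the shared subgraph grows.
`hier/colored.graphml` carries the per-gene color assignment (by highest
hierarchy node) for rendering.

Real data is consumed the same way: point `decompose` at a manifest of
SIF-style three-column interaction files, optionally with an
identifier-mapping table (`--mapping`) that marks nodes as gene/non-gene
and harmonizes identifiers across sources.

## Library use

```python
from pathkernel import (SynthSpec, generate_collection, build_catalog,
                        build_incidence, enumerate_maximal_bicliques,
                        build_hierarchy)

edge_lists, truth = generate_collection(SynthSpec(seed=7))
catalog, pathways = build_catalog(edge_lists)
bicliques = enumerate_maximal_bicliques(build_incidence(pathways))
hierarchy = build_hierarchy(bicliques)
```

See `docs/methods.md` for the model's assumptions, parameter defaults,
and known limitations.
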