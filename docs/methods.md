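# Methods

## Model

A pathway collection is modeled as a bipartite membership relation
between *edges* and *pathways*. An edge is a canonical unordered pair of
gene identifiers `(a, b)` with `a < b` lexicographically; every distinct
pair across the collection receives one integer id (consecutive from 1,
in lexicographic pair order, so the assignment is a pure function of the
pair set). A pathway is then a set of edge ids.

A **maximal biclique** of this relation is a pair (E, P) with every edge
of E present in every pathway of P, extendable on neither side. Bicliques
are exactly the shared subgraphs of the collection together with the
pathway group that shares them: E is the intersection of the edge sets of
P, and P is the full set of pathways containing E (biclique closure).

### Decomposition of mixed graphs

Input pathway files mix genes with non-gene entities. After identifier
harmonization (an optional mapping table supplies canonical ids and
gene/non-gene flags), gene–gene edges are obtained by path contraction:
genes g1, g2 form an edge when they are adjacent, or connected by a path
whose internal nodes are all non-gene and number at most
`max_internal_path`. An intermediate gene interrupts the path — the
relation is read as "connected through non-gene machinery", not as
transitive reachability. Interaction-type labels are ignored and all
relations treated as undirected, because nothing downstream consumes edge
semantics; self-loops (including pairs that collapse onto one canonical
cluster after mapping) are dropped and counted.

Implementation: one breadth-first search per gene, restricted to
non-gene interior nodes with a depth cap. If any qualifying simple path
exists, the shortest path through the non-gene-induced subgraph is no
longer, so the BFS bound is exact; the test suite checks this against an
all-simple-paths enumeration on random mixed graphs.

### Biclique enumeration

The pathway side of the relation is small relative to the edge side, so
enumeration works over pathway sets. Every maximal biclique's pathway
set is the intersection of the per-edge memberships of its edges; hence
all candidates lie in the closure of the family `{pathways(e)}` under
pairwise intersection. The enumerator computes that closure to a fixed
point, derives for each closed pathway set P the common edge set E, keeps
the pair when it is a closure fixed point and meets the size thresholds,
and deduplicates. Worst-case cost is exponential in the number of
*distinct* sharing patterns, not in pathways or edges; on collections
whose sharing structure is shallow (the practical case) it is fast. An
exhaustive oracle over all pathway subsets (guarded at 15 pathways)
provides the independent correctness reference.

### Hierarchy

Maximal bicliques are partially ordered by strict pathway-set containment;
closure makes this the inverse of edge-set containment, so along any
descending chain pathway groups shrink while shared subgraphs grow. The
hierarchy graph is the Hasse diagram (transitive reduction) of that
order. Levels are longest-path depths from the roots, guaranteeing a node
is drawn strictly below every node that contains it. Incomparable top
bicliques yield multiple roots; exports that need a tree add a virtual
super-root explicitly flagged as synthetic. Only maximal bicliques are
nodes — no intermediate non-maximal intersections are inserted.

### Components, augmentation, coloring

Each biclique's edge set is decoded into a gene graph and partitioned
into connected components by repeated breadth-first search over an
adjacency list (linear in vertices plus edges); the largest component
(LCC) summarizes the node. Before the root's LCC is taken, the root edge
set is augmented with the edges of every hierarchy node one or two
levels below it, measured on the hierarchy's level structure (not gene-graph
distance), so the top of the display carries the context of its
immediate refinements. Each gene is then colored by the highest
(minimum-level) hierarchy node whose LCC contains it; genes in no LCC
stay uncolored rather than inheriting a parent's color. Color indices
cycle a fixed 12-color palette by node id.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_internal_path` | 3 | max non-gene interior nodes a contracted path may use; 0 keeps direct edges only. Small by design: large values let hub molecules connect everything. A non-gene blacklist can exclude known currency metabolites entirely. |
| `unmapped_policy` | `drop` | nodes absent from the mapping table are dropped, or kept as non-gene / as gene. |
| `min_pathways` | 2 | a shared component must span at least two pathways; single-pathway bicliques carry no sharing signal. |
| `min_edges` | 1 | even a single shared edge is a reportable kernel. |

Tie-breaks are all deterministic: biclique output is sorted by (pathway
count desc, edge count desc, pathway ids); equal-sized components resolve
to the one with the lexicographically smallest member; equal-level color
candidates resolve to the smallest node id. Identifier comparison is
case-sensitive after whitespace trimming. Degenerate inputs are defined,
not errors: an empty interaction file is an empty graph, a pathway with
no gene edges is excluded with a warning, an empty biclique set yields an
empty hierarchy and empty exports.

## Synthetic data

The generator emulates the one property the method consumes: subsets of
pathways sharing planted subgraphs. A *kernel* is a block of random gene
pairs injected into a set of pathways; kernels form a laminar family
(pairwise disjoint or nested pathway sets), which makes the expected
biclique set analytic — each distinct kernel pathway set S yields exactly
the biclique (union of edges of kernels whose set contains S, S), and
pathway-private noise edges cannot create additional sharing at the
two-pathway threshold. Non-laminar plans are accepted; their ground
truth is computed by the exhaustive oracle instead.

Defaults: 60 genes, 8 pathways, four kernels of 2–4 edges arranged as a
six-pathway kernel refined by two three-pathway kernels and one
two-pathway kernel, plus 5 private noise edges per pathway — enough
structure for a three-level hierarchy with branching, at a size where
every cross-check (including exhaustive subset enumeration) is instant.
The spec carries an explicit pathway count (`n_pathways`) so noise can be
placed in pathways hosting no kernel. Gene labels are zero-padded
(`g0001…`) so lexicographic and numeric orders agree; all randomness
flows from one integer seed through a single generator, making
collections byte-reproducible.

What the generator does **not** emulate: realistic pathway topology
(scale-free degree structure, hub metabolites, densely overlapping
non-laminar sharing), non-gene nodes needing contraction (ingest is
exercised by its own mixed-graph tests instead), identifier noise, or
missing edges. Passing the recovery checks therefore demonstrates that
the machinery is exact on its own model — sharing that is literally
present is found, and only that — not that curated databases are free of
the alignment and completeness problems discussed under limitations.

## Verification sizes

The oracle cross-checks run at sizes where brute force is exact and
instant: 200 random incidences (≤ 10 pathways, ≤ 30 edges) for
enumeration, 200 random mixed graphs (≤ 12 nodes) for contraction, 200
random graphs (≤ 15 nodes) for components, 50 seeded collections for
recovery, and 60 random biclique sets for hierarchy invariants. These
sizes are the package's own verification protocol, chosen so the entire
suite completes in seconds while exercising every branch.

## Limitations

- Biclique enumeration is exponential in the worst case; collections with
  hundreds of pathways and adversarial sharing patterns may need the
  thresholds raised.
- The model is unweighted and undirected; interaction semantics,
  stoichiometry and direction are discarded at ingest.
- Shared-structure discovery is only as good as identifier
  harmonization: incomplete cross-species mappings fragment kernels that
  are biologically one. The mapping table is an input; no homology
  inference is performed.
- Summarizing bicliques by their LCC can hide shared structure outside
  the largest component; the full component partition is retained on each
  node for consumers that need it.
- Native BioPAX/RDF-OWL is out of scope; inputs are SIF-style exports.
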