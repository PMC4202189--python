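"""Materialize biclique edge sets as gene graphs and analyze connectivity.

A biclique's edge set, decoded through the catalog, is usually not a
connected graph, so each hierarchy node is summarized by its largest
connected component (LCC).  Components come from a breadth-first search
over an adjacency list — one BFS per not-yet-visited node — which runs in
time linear in vertices plus edges.  The root of a hierarchy is first
augmented with the edges of every node up to two levels below it, so the
kernel display carries the context of its immediate refinements; its LCC
is computed on that augmented graph.  Finally each gene is colored by the
highest (minimum-level) hierarchy node whose LCC contains it, giving a
visual key for how widely each gene's neighbourhood is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque
from typing import Iterable

from .bipartite import EdgeCatalog
from .hierarchy import HierarchyGraph
from .ingest import Pair

#: Fixed 12-color palette (colorblind-friendly hexes); color_index cycles
#: over it deterministically by biclique id.
PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02",
    "#a6761d", "#666666", "#1f78b4", "#b2df8a", "#fb9a99", "#cab2d6",
)


@dataclass
class ComponentGraph:
    """A biclique's gene graph with its component partition and LCC."""

    biclique_id: int
    gene_nodes: frozenset[str]
    gene_edges: frozenset[Pair]
    components: tuple[frozenset[str], ...]
    lcc_nodes: frozenset[str]
    lcc_edges: frozenset[Pair]


@dataclass(frozen=True)
class ColorAssignment:
    """gene -> (biclique id of its highest hierarchy node, color index)."""

    assignment: dict[str, tuple[int, int]]

    def color_of(self, gene: str) -> str | None:
        if gene not in self.assignment:
            return None
        return PALETTE[self.assignment[gene][1]]


def edges_to_graph(
    edge_ids: Iterable[int], catalog: EdgeCatalog
) -> tuple[frozenset[str], frozenset[Pair]]:
    """Decode edge ids into gene nodes and canonical gene pairs."""
    edges = set()
    nodes = set()
    for e in edge_ids:
        if e not in catalog.id_to_pair:
            raise KeyError(f"edge id {e} not in catalog")
        a, b = catalog.id_to_pair[e]
        edges.add((a, b))
        nodes.add(a)
        nodes.add(b)
    return frozenset(nodes), frozenset(edges)


def connected_components(
    gene_nodes: Iterable[str], gene_edges: Iterable[Pair]
) -> tuple[frozenset[str], ...]:
    """Partition nodes into connected components by repeated BFS.

    Builds an adjacency list, then starts one breadth-first search from
    each node not reached by a previous search; linear in nodes + edges.
    The partition is independent of visit order; the returned tuple is
    sorted by (size desc, smallest member) for determinism.
    """
    adj: dict[str, list[str]] = {n: [] for n in gene_nodes}
    for a, b in gene_edges:
        if a not in adj or b not in adj:
            raise KeyError(f"edge ({a!r}, {b!r}) references unknown node")
        adj[a].append(b)
        adj[b].append(a)

    seen: set[str] = set()
    parts: list[frozenset[str]] = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        seen.add(start)
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        parts.append(frozenset(comp))
    return tuple(sorted(parts, key=lambda c: (-len(c), min(c))))


def largest_component(partition: Iterable[frozenset[str]]) -> frozenset[str]:
    """Largest component; ties go to the lexicographically smallest member."""
    parts = list(partition)
    if not parts:
        raise ValueError("empty partition has no largest component")
    return min(parts, key=lambda c: (-len(c), min(c)))


def induced_edges(nodes: frozenset[str], edges: Iterable[Pair]) -> frozenset[Pair]:
    return frozenset((a, b) for a, b in edges if a in nodes and b in nodes)


def augment_root(
    h: HierarchyGraph, root_id: int, catalog: EdgeCatalog
) -> tuple[frozenset[str], frozenset[Pair]]:
    """Union the root's edges with those of nodes one or two levels below.

    Depth is measured on the hierarchy (arc distance from the root), not
    inside the gene graphs.  The root's LCC should be computed on this
    augmented edge set, so the top of the display shows the kernel plus
    its near refinements.
    """
    if root_id not in h.roots:
        raise KeyError(f"node {root_id!r} is not a root of the hierarchy")
    edge_ids = set(h.nodes[root_id].edge_ids)
    frontier = {root_id}
    for _ in range(2):
        frontier = {c for p, c in h.parent_child if p in frontier}
        for n in frontier:
            edge_ids |= h.nodes[n].edge_ids
    return edges_to_graph(edge_ids, catalog)


def build_component_graphs(
    h: HierarchyGraph, catalog: EdgeCatalog, augment_roots: bool = True
) -> dict[int, ComponentGraph]:
    """Compute the component summary for every hierarchy node.

    Roots are augmented with the two levels below them before their LCC
    is taken (unless ``augment_roots`` is off); other nodes use their own
    edge set.
    """
    out: dict[int, ComponentGraph] = {}
    for n in sorted(h.nodes):
        if augment_roots and n in h.roots:
            nodes, edges = augment_root(h, n, catalog)
        else:
            nodes, edges = edges_to_graph(h.nodes[n].edge_ids, catalog)
        parts = connected_components(nodes, edges)
        lcc = largest_component(parts) if parts else frozenset()
        out[n] = ComponentGraph(
            biclique_id=n,
            gene_nodes=nodes,
            gene_edges=edges,
            components=parts,
            lcc_nodes=lcc,
            lcc_edges=induced_edges(lcc, edges),
        )
    return out


def color_nodes(
    h: HierarchyGraph, component_graphs: dict[int, ComponentGraph]
) -> ColorAssignment:
    """Color each gene by the highest hierarchy node whose LCC contains it.

    "Highest" means minimum level; ties across incomparable nodes at the
    same level go to the smallest biclique id.  Genes in no LCC are left
    uncolored.  color_index = biclique_id mod palette size.
    """
    best: dict[str, tuple[int, int]] = {}  # gene -> (level, biclique_id)
    for n in sorted(component_graphs):
        level = h.levels[n]
        for gene in component_graphs[n].lcc_nodes:
            if gene not in best or (level, n) < best[gene]:
                best[gene] = (level, n)
    return ColorAssignment(
        {g: (n, n % len(PALETTE)) for g, (_, n) in sorted(best.items())}
    )


def colored_graphml(
    component_graphs: dict[int, ComponentGraph],
    colors: ColorAssignment,
    h: HierarchyGraph,
    catalog: EdgeCatalog,
) -> str:
    """GraphML for the union of all LCCs with color/level/edge attributes."""
    import io

    import networkx as nx

    g = nx.Graph()
    all_genes: set[str] = set()
    all_edges: set[Pair] = set()
    for cg in component_graphs.values():
        all_genes |= cg.lcc_nodes
        all_edges |= cg.lcc_edges
    for gene in sorted(all_genes):
        if gene in colors.assignment:
            bid, cidx = colors.assignment[gene]
            g.add_node(gene, biclique_id=bid, color_index=cidx,
                       level=h.levels[bid])
        else:
            g.add_node(gene, biclique_id=-1, color_index=-1, level=-1)
    for a, b in sorted(all_edges):
        g.add_edge(a, b, edge_id=catalog.pair_to_id[(a, b)])
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode("utf-8")


def colored_dot(
    component_graphs: dict[int, ComponentGraph], colors: ColorAssignment
) -> str:
    """DOT rendering of the union of LCCs with palette fill colors."""
    lines = ["graph colored_components {", "  node [style=filled];"]
    all_genes: set[str] = set()
    all_edges: set[Pair] = set()
    for cg in component_graphs.values():
        all_genes |= cg.lcc_nodes
        all_edges |= cg.lcc_edges
    for gene in sorted(all_genes):
        fill = colors.color_of(gene) or "#ffffff"
        lines.append(f'  "{gene}" [fillcolor="{fill}"];')
    for a, b in sorted(all_edges):
        lines.append(f'  "{a}" -- "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
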