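"""Arrange maximal bicliques into a containment hierarchy.

Bicliques are partially ordered: one sits above another when its pathway
set strictly contains the other's (equivalently, by biclique closure, its
edge set is strictly contained).  The hierarchy graph is the Hasse
diagram (transitive reduction) of that order.  The top node aggregates
the most pathways — the kernel shared most widely — and descending the
hierarchy trades pathway breadth for edge detail.  Multiple roots arise
when pathway sets are incomparable; exports needing a single tree root
add a virtual super-root flagged as synthetic.

Levels are longest-path depths from the roots, so a node is always drawn
strictly below every node whose pathway set contains its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .bipartite import Biclique


@dataclass
class HierarchyGraph:
    """DAG of bicliques ordered by strict pathway-set containment.

    ``parent_child`` is the transitive reduction of the order; ``levels``
    maps each node to its longest-path depth from the roots (roots at 0).
    Node ids are consecutive integers assigned in the deterministic
    biclique sort order.
    """

    nodes: dict[int, Biclique] = field(default_factory=dict)
    parent_child: set[tuple[int, int]] = field(default_factory=set)
    levels: dict[int, int] = field(default_factory=dict)
    roots: frozenset[int] = frozenset()

    def children(self, node_id: int) -> list[int]:
        return sorted(c for p, c in self.parent_child if p == node_id)

    def parents(self, node_id: int) -> list[int]:
        return sorted(p for p, c in self.parent_child if c == node_id)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.parent_child))
        return g

    def __len__(self) -> int:
        return len(self.nodes)


def _levels_from(g: nx.DiGraph) -> dict[int, int]:
    """Longest-path depth (in-degree-0 nodes at depth 0)."""
    levels = {n: 0 for n in g.nodes}
    for n in nx.topological_sort(g):
        for child in g.successors(n):
            levels[child] = max(levels[child], levels[n] + 1)
    return levels


def build_hierarchy(bicliques: list[Biclique]) -> HierarchyGraph:
    """Build the Hasse diagram of strict pathway-set containment.

    An arc runs parent -> child when pathways(parent) strictly contains
    pathways(child) and no third biclique sits strictly between them.
    For maximal bicliques this inverts edge-set containment, so along any
    arc pathways shrink while edges grow.  Node ids follow the
    deterministic biclique sort order; empty input gives an empty graph.
    """
    distinct = set(bicliques)
    if len(distinct) != len(bicliques):
        raise ValueError("bicliques must be pairwise distinct")
    ordered = sorted(distinct, key=Biclique.sort_key)
    nodes = dict(enumerate(ordered))
    if not nodes:
        return HierarchyGraph()

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i, bi in nodes.items():
        for j, bj in nodes.items():
            if i != j and bi.pathway_ids > bj.pathway_ids:
                g.add_edge(i, j)
    reduced = nx.transitive_reduction(g)
    roots = {n for n in nodes if reduced.in_degree(n) == 0}
    return HierarchyGraph(
        nodes=nodes,
        parent_child=set(reduced.edges),
        levels=_levels_from(reduced),
        roots=frozenset(roots),
    )


def subhierarchy(h: HierarchyGraph, root_id: int) -> HierarchyGraph:
    """Induced hierarchy on a node and its descendants, re-rooted there."""
    if root_id not in h.nodes:
        raise KeyError(f"unknown hierarchy node {root_id!r}")
    g = h.to_digraph()
    keep = {root_id} | nx.descendants(g, root_id)
    sub = g.subgraph(keep).copy()
    return HierarchyGraph(
        nodes={n: h.nodes[n] for n in sorted(keep)},
        parent_child=set(sub.edges),
        levels=_levels_from(sub),
        roots=frozenset({root_id}),
    )


def pathway_view(h: HierarchyGraph) -> tuple[
    dict[int, frozenset[str]], set[tuple[int, int]]
]:
    """Relabel hierarchy nodes by their pathway groups, keeping the arcs.

    This is the view of how the original pathways nest: each node becomes
    the set of pathway ids it aggregates, and an arc means the parent
    group strictly contains the child group.
    """
    return {n: b.pathway_ids for n, b in h.nodes.items()}, set(h.parent_child)


def hierarchy_to_json_obj(h: HierarchyGraph) -> dict:
    """JSON-ready dict: nodes with payloads and levels, plus arc list."""
    return {
        "nodes": [
            {
                "id": n,
                "edge_ids": sorted(b.edge_ids),
                "pathway_ids": sorted(b.pathway_ids),
                "level": h.levels[n],
            }
            for n, b in sorted(h.nodes.items())
        ],
        "arcs": sorted([p, c] for p, c in h.parent_child),
    }


def hierarchy_to_dot(h: HierarchyGraph, single_root: bool = False) -> str:
    """Render the hierarchy as DOT, one rank per level.

    With ``single_root`` a virtual super-root labelled as synthetic is
    added above all real roots, for consumers that require a tree.
    """
    lines = ["digraph hierarchy {", "  rankdir=TB;"]
    for n, b in sorted(h.nodes.items()):
        label = f"n{n}\\n{b.n_pathways} pathways / {b.n_edges} edges"
        lines.append(f'  n{n} [label="{label}"];')
    if single_root and len(h.roots) != 1:
        lines.append('  superroot [label="(synthetic super-root)", style=dashed];')
        for r in sorted(h.roots):
            lines.append(f"  superroot -> n{r} [style=dashed];")
    for p, c in sorted(h.parent_child):
        lines.append(f"  n{p} -> n{c};")
    by_level: dict[int, list[int]] = {}
    for n, lv in h.levels.items():
        by_level.setdefault(lv, []).append(n)
    for lv in sorted(by_level):
        members = " ".join(f"n{n};" for n in sorted(by_level[lv]))
        lines.append(f"  {{ rank=same; {members} }}")
    lines.append("}")
    return "\n".join(lines) + "\n"
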