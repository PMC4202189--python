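"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pathkernel import (
    BipartiteIncidence,
    MixedGraph,
    PathwayEdgeSet,
    build_incidence,
    canonical_pair,
)


def incidence_from_dict(pathway_edges: dict[str, set[int]]) -> BipartiteIncidence:
    """Build an incidence from {pathway_id: edge id set}."""
    return build_incidence([
        PathwayEdgeSet(pid, pid, "test", frozenset(edges))
        for pid, edges in pathway_edges.items()
    ])


def random_incidence(rng: np.random.Generator) -> BipartiteIncidence:
    """Random incidence: <= 10 pathways, <= 30 edges, random density."""
    n_pathways = int(rng.integers(1, 11))
    n_edges = int(rng.integers(1, 31))
    density = float(rng.uniform(0.05, 0.6))
    pathway_edges: dict[str, set[int]] = {}
    for i in range(n_pathways):
        edges = {e + 1 for e in range(n_edges) if rng.random() < density}
        if not edges:
            edges = {int(rng.integers(1, n_edges + 1))}
        pathway_edges[f"P{i:02d}"] = edges
    return incidence_from_dict(pathway_edges)


def random_mixed_graph(rng: np.random.Generator, max_nodes: int = 12) -> MixedGraph:
    """Random gene/non-gene graph for interpolation testing."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i:02d}" for i in range(n)]
    nodes = {name: bool(rng.random() < 0.5) for name in names}
    adjacency = set()
    p = float(rng.uniform(0.1, 0.5))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adjacency.add(canonical_pair(names[i], names[j]))
    return MixedGraph("synthetic", nodes, adjacency)


def interpolation_oracle(graph: MixedGraph, max_internal_path: int) -> frozenset:
    """All-simple-paths reference for gene-edge interpolation.

    Enumerates every simple path of length <= max_internal_path + 1 and
    keeps gene endpoints whose path interiors are entirely non-gene.
    Exponential; only for tiny graphs.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.adjacency)
    genes = sorted(n for n, is_gene in graph.nodes.items() if is_gene)
    pairs = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            for path in nx.all_simple_paths(g, a, b, cutoff=max_internal_path + 1):
                interior = path[1:-1]
                if all(not graph.nodes[v] for v in interior):
                    pairs.add(canonical_pair(a, b))
                    break
    return frozenset(pairs)


def union_find_partition(nodes, edges) -> set[frozenset]:
    """Union-find reference partition for connected components."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140)
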