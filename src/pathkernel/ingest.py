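"""Read pathway network files and reduce them to discrete gene-gene edges.

Pathway exports mix genes with non-gene entities (small molecules,
complexes, reaction nodes).  The model downstream only understands
gene-gene edges, so ingestion proceeds in three steps:

1. :func:`read_sif` parses a SIF-style three-column interaction file into a
   :class:`MixedGraph` of undirected node pairs.
2. :func:`apply_mapping` harmonizes identifiers onto canonical cluster ids
   and marks each node as gene or non-gene.
3. :func:`interpolate_gene_edges` contracts paths that run through
   non-gene nodes: two genes become an edge when they are directly
   adjacent, or joined by a path whose internal nodes are *all* non-gene
   (an intermediate gene interrupts the path).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

log = logging.getLogger(__name__)

#: Default bound on the number of internal non-gene nodes a contracted
#: path may traverse.  Keeps contraction local so that promiscuous
#: non-gene hubs (e.g. currency metabolites) do not connect everything.
DEFAULT_MAX_INTERNAL_PATH = 3

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order a node pair lexicographically so unordered pairs compare equal."""
    return (a, b) if a < b else (b, a)


class SifParseError(ValueError):
    """Raised for a malformed interaction line; carries the line number."""

    def __init__(self, line_number: int, line: str):
        self.line_number = line_number
        super().__init__(
            f"line {line_number}: expected 3 tab-separated columns, got {line!r}"
        )


class UnmappedPolicy(str, Enum):
    """What to do with nodes absent from the identifier mapping."""

    DROP = "drop"
    KEEP_AS_NONGENE = "keep-as-nongene"
    KEEP_AS_GENE = "keep-as-gene"


@dataclass
class MixedGraph:
    """An undirected pathway graph whose nodes may be genes or non-genes.

    ``adjacency`` holds canonically ordered unordered pairs; self-loops are
    never stored (they are dropped at parse or mapping time and counted).
    """

    pathway_id: str
    nodes: dict[str, bool] = field(default_factory=dict)  # node id -> is_gene
    adjacency: set[Pair] = field(default_factory=set)
    dropped_self_loops: int = 0
    unmapped_nodes: int = 0

    def __post_init__(self) -> None:
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"self-loop stored in adjacency: {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"pair ({a!r}, {b!r}) references unknown node")


@dataclass(frozen=True)
class IdMapping:
    """Map from original node ids to (canonical id, is_gene)."""

    entries: Mapping[str, tuple[str, bool]]

    def __post_init__(self) -> None:
        for orig, (canon, _) in self.entries.items():
            if not canon:
                raise ValueError(f"empty canonical id for {orig!r}")


@dataclass(frozen=True)
class GeneEdgeList:
    """A pathway reduced to canonically ordered gene-gene pairs."""

    pathway_id: str
    gene_pairs: frozenset[Pair]

    def __post_init__(self) -> None:
        for a, b in self.gene_pairs:
            if a >= b:
                raise ValueError(f"pair ({a!r}, {b!r}) not canonically ordered")


def read_sif(stream: Iterable[str], pathway_id: str) -> MixedGraph:
    """Parse SIF-style ``A<TAB>interaction<TAB>B`` lines into a MixedGraph.

    Interaction types are discarded: every line becomes one undirected
    node pair, deduplicated across lines and orientations.  Blank lines
    and ``#`` comments are skipped; self-referential lines are dropped and
    counted.  All nodes start flagged as genes until a mapping says
    otherwise.
    """
    nodes: dict[str, bool] = {}
    adjacency: set[Pair] = set()
    dropped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise SifParseError(lineno, line)
        a, b = cols[0].strip(), cols[2].strip()
        if not a or not b:
            raise SifParseError(lineno, line)
        if a == b:
            dropped += 1
            continue
        nodes.setdefault(a, True)
        nodes.setdefault(b, True)
        adjacency.add(canonical_pair(a, b))
    if dropped:
        log.info("%s: dropped %d self-loop line(s)", pathway_id, dropped)
    return MixedGraph(pathway_id, nodes, adjacency, dropped_self_loops=dropped)


def apply_mapping(
    graph: MixedGraph,
    mapping: IdMapping,
    unmapped_policy: UnmappedPolicy | str = UnmappedPolicy.DROP,
) -> MixedGraph:
    """Relabel nodes onto canonical ids and set gene flags from the mapping.

    Pairs that collapse to self-loops after relabeling (two originals
    mapping to one canonical cluster) are dropped and counted.  Unmapped
    nodes are dropped or kept, per ``unmapped_policy``; kept nodes retain
    their original id.
    """
    policy = UnmappedPolicy(unmapped_policy)
    relabel: dict[str, str] = {}
    nodes: dict[str, bool] = {}
    n_unmapped = 0
    for node in graph.nodes:
        if node in mapping.entries:
            canon, is_gene = mapping.entries[node]
        else:
            n_unmapped += 1
            if policy is UnmappedPolicy.DROP:
                continue
            canon = node
            is_gene = policy is UnmappedPolicy.KEEP_AS_GENE
        relabel[node] = canon
        # A canonical id reached from several originals is a gene if any
        # of them says so; in practice mappings are consistent per cluster.
        nodes[canon] = nodes.get(canon, False) or is_gene

    adjacency: set[Pair] = set()
    collapsed = graph.dropped_self_loops
    for a, b in graph.adjacency:
        if a not in relabel or b not in relabel:
            continue  # endpoint dropped by policy
        ca, cb = relabel[a], relabel[b]
        if ca == cb:
            collapsed += 1
            continue
        adjacency.add(canonical_pair(ca, cb))
    if n_unmapped:
        log.info(
            "%s: %d unmapped node(s) handled by policy %s",
            graph.pathway_id, n_unmapped, policy.value,
        )
    # prune nodes that lost all their pairs only under DROP-collapse? No:
    # isolated nodes are legitimate (they carry no edges downstream).
    return MixedGraph(
        graph.pathway_id,
        nodes,
        adjacency,
        dropped_self_loops=collapsed,
        unmapped_nodes=n_unmapped,
    )


def interpolate_gene_edges(
    graph: MixedGraph,
    max_internal_path: int = DEFAULT_MAX_INTERNAL_PATH,
    nongene_blacklist: frozenset[str] | set[str] = frozenset(),
) -> GeneEdgeList:
    """Contract non-gene paths into direct gene-gene edges.

    Returns exactly the pairs of distinct genes that are adjacent, or
    joined by a path whose internal nodes are all non-gene, not
    blacklisted, and number at most ``max_internal_path``.  A gene on the
    path interrupts it: no edge is created across an intermediate gene.
    ``max_internal_path=0`` keeps direct gene-gene adjacency only.

    A breadth-first search from each gene through non-gene nodes finds
    these pairs: if any qualifying simple path exists, the shortest path
    through the non-gene interior is no longer, so a BFS depth bound
    suffices.
    """
    if max_internal_path < 0:
        raise ValueError("max_internal_path must be >= 0")
    blacklist = frozenset(nongene_blacklist)

    neighbors: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for a, b in graph.adjacency:
        neighbors[a].add(b)
        neighbors[b].add(a)

    genes = sorted(n for n, is_gene in graph.nodes.items() if is_gene)
    pairs: set[Pair] = set()
    for g in genes:
        # BFS over non-gene interior nodes; depth = internal nodes used so far.
        seen: set[str] = {g}
        frontier: deque[tuple[str, int]] = deque([(g, 0)])
        while frontier:
            node, depth = frontier.popleft()
            for nb in neighbors[node]:
                if graph.nodes[nb]:  # neighbor is a gene: emit, do not traverse
                    if nb != g:
                        pairs.add(canonical_pair(g, nb))
                    continue
                if nb in seen or nb in blacklist or depth >= max_internal_path:
                    continue
                seen.add(nb)
                frontier.append((nb, depth + 1))
    return GeneEdgeList(graph.pathway_id, frozenset(pairs))
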