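"""Edge catalog, edges-by-pathways incidence, and maximal biclique enumeration.

Each distinct gene-gene pair observed anywhere in the collection gets one
integer edge id; a pathway then becomes a plain set of edge ids.  The
edges-by-pathways membership relation is a bipartite graph, and a maximal
biclique in it is a set of edges E and a set of pathways P such that every
edge of E occurs in every pathway of P, with neither side extendable.
These bicliques are the shared subgraphs the whole toolkit exists to find.

Enumeration uses a closure (consensus) construction over pathway-set
intersections, exploiting that the pathway side is small relative to the
edge side: every maximal biclique's pathway set is an intersection of the
per-edge pathway memberships, so closing the family of memberships under
pairwise intersection visits every candidate exactly once.  A brute-force
oracle over pathway subsets (:func:`oracle_enumerate`) provides an
independent cross-check on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ingest import GeneEdgeList, Pair

log = logging.getLogger(__name__)

#: A shared component must span at least this many pathways by default;
#: a biclique confined to a single pathway carries no sharing signal.
DEFAULT_MIN_PATHWAYS = 2
DEFAULT_MIN_EDGES = 1

#: Instance-size guard for the brute-force oracle (2^n pathway subsets).
ORACLE_MAX_PATHWAYS = 15


@dataclass(frozen=True)
class EdgeCatalog:
    """Bijection between canonical gene pairs and consecutive integer ids.

    Ids start at 1 and follow the lexicographic order of the canonical
    pairs, so the assignment is a pure function of the pair set.
    """

    pair_to_id: dict[Pair, int]
    id_to_pair: dict[int, Pair]

    @classmethod
    def from_pairs(cls, pairs: set[Pair] | frozenset[Pair]) -> "EdgeCatalog":
        pair_to_id = {p: i for i, p in enumerate(sorted(pairs), start=1)}
        return cls(pair_to_id, {i: p for p, i in pair_to_id.items()})

    def __post_init__(self) -> None:
        if len(self.pair_to_id) != len(self.id_to_pair):
            raise ValueError("pair_to_id and id_to_pair are not a bijection")
        for p, i in self.pair_to_id.items():
            if self.id_to_pair.get(i) != p:
                raise ValueError("pair_to_id and id_to_pair are not inverse maps")

    def __len__(self) -> int:
        return len(self.pair_to_id)


@dataclass(frozen=True)
class PathwayEdgeSet:
    """A pathway reduced to the ids of its gene-gene edges."""

    pathway_id: str
    name: str
    source: str
    edge_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.edge_ids:
            raise ValueError(f"pathway {self.pathway_id!r} has no edges")


@dataclass(frozen=True)
class BipartiteIncidence:
    """Transpose-consistent edge->pathways and pathway->edges maps."""

    edge_to_pathways: dict[int, frozenset[str]]
    pathway_to_edges: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        recon: dict[int, set[str]] = {}
        for p, edges in self.pathway_to_edges.items():
            if not edges:
                raise ValueError(f"pathway {p!r} has an empty edge set")
            for e in edges:
                recon.setdefault(e, set()).add(p)
        if {e: frozenset(ps) for e, ps in recon.items()} != self.edge_to_pathways:
            raise ValueError("edge_to_pathways is not the transpose of pathway_to_edges")


@dataclass(frozen=True)
class Biclique:
    """A maximal (edge set, pathway set) pair: the unit of shared structure."""

    edge_ids: frozenset[int]
    pathway_ids: frozenset[str]

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def sort_key(self) -> tuple:
        return (-self.n_pathways, -self.n_edges, sorted(self.pathway_ids))


def build_catalog(
    edge_lists: list[GeneEdgeList],
    names: dict[str, str] | None = None,
    sources: dict[str, str] | None = None,
) -> tuple[EdgeCatalog, list[PathwayEdgeSet]]:
    """Assign one id per distinct pair and express pathways as id sets.

    Ids depend only on the union of pairs, so permuting the input list
    (or reordering lines within a pathway) cannot change them.  Pathways
    with zero pairs are excluded with a warning.
    """
    names = names or {}
    sources = sources or {}
    all_pairs: set[Pair] = set()
    kept: list[GeneEdgeList] = []
    for el in edge_lists:
        if not el.gene_pairs:
            log.warning("pathway %r has no gene edges; excluded", el.pathway_id)
            continue
        kept.append(el)
        all_pairs.update(el.gene_pairs)
    catalog = EdgeCatalog.from_pairs(all_pairs)
    pathways = [
        PathwayEdgeSet(
            pathway_id=el.pathway_id,
            name=names.get(el.pathway_id, el.pathway_id),
            source=sources.get(el.pathway_id, ""),
            edge_ids=frozenset(catalog.pair_to_id[p] for p in el.gene_pairs),
        )
        for el in kept
    ]
    return catalog, pathways


def build_incidence(pathways: list[PathwayEdgeSet]) -> BipartiteIncidence:
    """Build the edges-by-pathways membership structure."""
    if not pathways:
        raise ValueError("pathway list is empty")
    seen: set[str] = set()
    for p in pathways:
        if p.pathway_id in seen:
            raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
        seen.add(p.pathway_id)
    pathway_to_edges = {p.pathway_id: p.edge_ids for p in pathways}
    edge_to_pathways: dict[int, set[str]] = {}
    for p in pathways:
        for e in p.edge_ids:
            edge_to_pathways.setdefault(e, set()).add(p.pathway_id)
    return BipartiteIncidence(
        {e: frozenset(ps) for e, ps in edge_to_pathways.items()},
        pathway_to_edges,
    )


def enumerate_maximal_bicliques(
    incidence: BipartiteIncidence,
    min_pathways: int = DEFAULT_MIN_PATHWAYS,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> list[Biclique]:
    """Enumerate every maximal biclique meeting the size thresholds.

    Closure construction: the pathway set of any maximal biclique with a
    nonempty edge set equals the intersection of the per-edge memberships
    of its edges, hence lies in the intersection-closure of the family
    ``{pathways(e)}``.  The family is closed under pairwise intersection
    to a fixed point; each closed pathway set P then yields the biclique
    (edges common to all of P, P), deduplicated.  Output is sorted by
    (pathway count desc, edge count desc, pathway ids) for determinism.
    """
    if min_pathways < 1 or min_edges < 1:
        raise ValueError("min_pathways and min_edges must be >= 1")

    memberships = set(incidence.edge_to_pathways.values())
    closed: set[frozenset[str]] = set(memberships)
    worklist = list(closed)
    while worklist:
        a = worklist.pop()
        for b in list(closed):
            c = a & b
            if c and c not in closed:
                closed.add(c)
                worklist.append(c)

    results: set[Biclique] = set()
    for pset in closed:
        if len(pset) < min_pathways:
            continue
        edges = frozenset(
            e for e, ps in incidence.edge_to_pathways.items() if pset <= ps
        )
        if len(edges) < min_edges:
            continue
        # Maximality on the pathway side: pathways containing all of E.
        # By construction pset is an intersection of the memberships of
        # its edges, so this recomputation is a fixed point, asserted
        # cheaply here.
        full = frozenset.intersection(*(incidence.edge_to_pathways[e] for e in edges))
        if full != pset:
            continue  # pset not closed for its edge set; its closure is also visited
        results.add(Biclique(edges, pset))
    return sorted(results, key=Biclique.sort_key)


def oracle_enumerate(
    incidence: BipartiteIncidence,
    min_pathways: int = DEFAULT_MIN_PATHWAYS,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> list[Biclique]:
    """Brute-force reference enumeration over all pathway subsets.

    For every nonempty subset S of pathways, intersect their edge sets to
    get E, re-expand to P = all pathways containing E, and keep (E, P)
    when nonempty and within thresholds.  Complete by construction;
    refuses instances above ``ORACLE_MAX_PATHWAYS`` pathways.
    """
    from itertools import combinations

    ids = sorted(incidence.pathway_to_edges)
    if len(ids) > ORACLE_MAX_PATHWAYS:
        raise ValueError(
            f"oracle limited to {ORACLE_MAX_PATHWAYS} pathways, got {len(ids)}"
        )
    results: set[Biclique] = set()
    for r in range(1, len(ids) + 1):
        for subset in combinations(ids, r):
            edges = frozenset.intersection(
                *(incidence.pathway_to_edges[p] for p in subset)
            )
            if not edges:
                continue
            pset = frozenset(
                p for p, es in incidence.pathway_to_edges.items() if edges <= es
            )
            if len(pset) >= min_pathways and len(edges) >= min_edges:
                results.add(Biclique(edges, pset))
    return sorted(results, key=Biclique.sort_key)
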