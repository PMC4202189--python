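"""Generate synthetic pathway collections with planted shared kernels.

Real pathway collections are interesting precisely because subsets of
pathways share subgraphs.  The generator plants that structure directly:
a *kernel* is a block of gene-gene edges injected into a chosen set of
pathways, and kernels are organized as a laminar family (any two pathway
sets disjoint or nested) so the maximal bicliques the collection must
yield are known in closed form.  Pathway-private noise edges are then
added; being unique to one pathway they can never create a shared
biclique at a two-pathway threshold, so recovery of the planted structure
should be exact.

Non-laminar kernel plans are accepted too; their ground truth is
computed by the brute-force subset oracle instead of the closed form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .bipartite import (
    Biclique,
    EdgeCatalog,
    build_catalog,
    build_incidence,
    oracle_enumerate,
)
from .ingest import GeneEdgeList, Pair, canonical_pair


@dataclass(frozen=True)
class SynthSpec:
    """Blueprint for one synthetic collection.

    ``kernel_plan`` lists (edge_count, pathway_indices) blocks; indices
    are 0-based into ``n_pathways`` pathways.  With ``laminar`` plans the
    expected biclique set is analytic; otherwise it is derived by oracle.
    """

    n_genes: int = 60
    n_pathways: int = 8
    kernel_plan: tuple[tuple[int, frozenset[int]], ...] = (
        (2, frozenset({0, 1, 2, 3, 4, 5})),
        (3, frozenset({0, 1, 2})),
        (4, frozenset({0, 1})),
        (3, frozenset({3, 4, 5})),
    )
    noise_edges_per_pathway: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_pathways < 1:
            raise ValueError("need at least 2 genes and 1 pathway")
        for count, pset in self.kernel_plan:
            if count < 1:
                raise ValueError("kernel edge counts must be >= 1")
            if not pset or not all(0 <= i < self.n_pathways for i in pset):
                raise ValueError("kernel pathway indices out of range")
        total = (
            sum(c for c, _ in self.kernel_plan)
            + self.n_pathways * self.noise_edges_per_pathway
        )
        if total > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError(
                f"spec infeasible: {total} distinct edges requested but only "
                f"{self.n_genes * (self.n_genes - 1) // 2} gene pairs exist"
            )

    @property
    def is_laminar(self) -> bool:
        """Any two kernel pathway sets are disjoint or nested."""
        sets = [pset for _, pset in self.kernel_plan]
        for a, b in itertools.combinations(sets, 2):
            if a & b and not (a <= b or b <= a):
                return False
        return True


@dataclass(frozen=True)
class GroundTruth:
    """Planted bicliques, in gene-pair space, expected from enumeration.

    Computed for the default thresholds (at least two pathways, at least
    one edge); kernels spanning a single pathway are planted but do not
    appear here.
    """

    bicliques: frozenset[tuple[frozenset[Pair], frozenset[str]]]
    kernel_pairs: tuple[frozenset[Pair], ...] = field(default=())


def _pathway_label(i: int, n: int) -> str:
    width = max(2, len(str(n - 1)))
    return f"P{i:0{width}d}"


def _gene_label(i: int) -> str:
    return f"g{i:04d}"


def _sample_distinct_pairs(
    rng: np.random.Generator, n_genes: int, count: int, used: set[Pair]
) -> list[Pair]:
    """Draw `count` gene pairs not yet in `used`, updating `used`."""
    out: list[Pair] = []
    while len(out) < count:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        pair = canonical_pair(_gene_label(int(i)), _gene_label(int(j)))
        if pair in used:
            continue
        used.add(pair)
        out.append(pair)
    return out


def generate_collection(spec: SynthSpec) -> tuple[list[GeneEdgeList], GroundTruth]:
    """Build the pathway edge lists and the biclique ground truth.

    Every kernel's edges appear in exactly its pathway set; noise edges
    are pathway-private and globally distinct from everything else, so
    they cannot manufacture sharing.  Output is a pure function of the
    spec (the spec's seed drives all randomness).
    """
    rng = np.random.default_rng(spec.seed)
    used: set[Pair] = set()
    kernel_pairs = [
        frozenset(_sample_distinct_pairs(rng, spec.n_genes, count, used))
        for count, _ in spec.kernel_plan
    ]

    labels = [_pathway_label(i, spec.n_pathways) for i in range(spec.n_pathways)]
    pathway_pairs: dict[str, set[Pair]] = {lab: set() for lab in labels}
    for pairs, (_, pset) in zip(kernel_pairs, spec.kernel_plan):
        for i in pset:
            pathway_pairs[labels[i]] |= pairs
    for lab in labels:
        pathway_pairs[lab].update(
            _sample_distinct_pairs(rng, spec.n_genes, spec.noise_edges_per_pathway, used)
        )

    edge_lists = [
        GeneEdgeList(lab, frozenset(pathway_pairs[lab])) for lab in labels
    ]
    truth = _ground_truth(spec, kernel_pairs, edge_lists, labels)
    return edge_lists, GroundTruth(truth, tuple(kernel_pairs))


def _ground_truth(
    spec: SynthSpec,
    kernel_pairs: list[frozenset[Pair]],
    edge_lists: list[GeneEdgeList],
    labels: list[str],
) -> frozenset[tuple[frozenset[Pair], frozenset[str]]]:
    if spec.is_laminar:
        # Closed form: each distinct kernel pathway set S yields the
        # biclique (union of edges of kernels whose set contains S, S).
        by_set: dict[frozenset[int], set[Pair]] = {}
        for pairs, (_, pset) in zip(kernel_pairs, spec.kernel_plan):
            by_set.setdefault(pset, set()).update(pairs)
        out = set()
        for pset in by_set:
            if len(pset) < 2:
                continue
            edges = frozenset().union(
                *(pairs for s, pairs in by_set.items() if pset <= s)
            )
            out.add((frozenset(edges), frozenset(labels[i] for i in pset)))
        return frozenset(out)
    # General plans: delegate to the exhaustive oracle.
    catalog, pathways = build_catalog(edge_lists)
    found = oracle_enumerate(build_incidence(pathways), min_pathways=2, min_edges=1)
    return frozenset(_decode(b, catalog) for b in found)


def _decode(b: Biclique, catalog: EdgeCatalog) -> tuple[frozenset[Pair], frozenset[str]]:
    return (
        frozenset(catalog.id_to_pair[e] for e in b.edge_ids),
        b.pathway_ids,
    )


def score_recovery(
    found: list[Biclique], truth: GroundTruth, catalog: EdgeCatalog
) -> tuple[float, float]:
    """Exact-match precision and recall of found bicliques against truth.

    Comparison happens in gene-pair space so it is independent of edge-id
    assignment.  Empty found with empty truth scores (1.0, 1.0); empty
    found against nonempty truth scores precision 1.0 by convention and
    recall 0.0.
    """
    found_set = {_decode(b, catalog) for b in found}
    truth_set = set(truth.bicliques)
    tp = len(found_set & truth_set)
    precision = tp / len(found_set) if found_set else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return precision, recall
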