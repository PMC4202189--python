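"""Gene-graph materialization, BFS components, root augmentation, coloring."""

from __future__ import annotations

import pytest

from pathkernel import (
    Biclique,
    EdgeCatalog,
    augment_root,
    build_component_graphs,
    build_hierarchy,
    color_nodes,
    connected_components,
    edges_to_graph,
    largest_component,
)
from conftest import union_find_partition


def catalog_of(*pairs) -> EdgeCatalog:
    return EdgeCatalog.from_pairs(set(pairs))


class TestEdgesToGraph:
    def test_decodes_single_edge(self):
        cat = catalog_of(("A", "B"))
        nodes, edges = edges_to_graph({1}, cat)
        assert nodes == {"A", "B"} and edges == {("A", "B")}

    def test_empty_id_set(self):
        nodes, edges = edges_to_graph(set(), catalog_of(("A", "B")))
        assert nodes == frozenset() and edges == frozenset()

    def test_path_graph(self):
        cat = catalog_of(("A", "B"), ("B", "C"))
        nodes, edges = edges_to_graph({1, 2}, cat)
        assert nodes == {"A", "B", "C"} and edges == {("A", "B"), ("B", "C")}

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            edges_to_graph({42}, catalog_of(("A", "B")))


class TestConnectedComponents:
    def test_two_separate_pairs(self):
        parts = connected_components({"A", "B", "C", "D"}, {("A", "B"), ("C", "D")})
        assert set(parts) == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_isolated_node_is_its_own_component(self):
        assert connected_components({"A"}, set()) == (frozenset({"A"}),)

    def test_matches_union_find_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 16))
            nodes = {f"v{i:02d}" for i in range(n)}
            names = sorted(nodes)
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        edges.add((names[i], names[j]))
            assert set(connected_components(nodes, edges)) == \
                union_find_partition(nodes, edges)

    def test_partition_independent_of_edge_order(self, rng):
        nodes = {"a", "b", "c", "d", "e"}
        edges = [("a", "b"), ("b", "c"), ("d", "e")]
        base = set(connected_components(nodes, set(edges)))
        for _ in range(5):
            perm = [edges[i] for i in rng.permutation(len(edges))]
            assert set(connected_components(nodes, set(perm))) == base


class TestLargestComponent:
    def test_picks_maximum(self):
        parts = [frozenset({"A", "B", "C"}), frozenset({"D", "E"})]
        assert largest_component(parts) == {"A", "B", "C"}

    def test_tie_broken_by_smallest_member(self):
        parts = [frozenset({"C", "D"}), frozenset({"A", "B"})]
        assert largest_component(parts) == {"A", "B"}

    def test_single_component_identity(self):
        assert largest_component([frozenset({"A"})]) == {"A"}

    def test_empty_partition_raises(self):
        with pytest.raises(ValueError):
            largest_component([])


class TestAugmentRoot:
    def hierarchy_chain(self, *edge_sets):
        """Chain of bicliques with shrinking pathway sets, growing edges."""
        n = len(edge_sets)
        bicliques = [
            Biclique(frozenset(es), frozenset(f"P{j}" for j in range(n - i)))
            for i, es in enumerate(edge_sets)
        ]
        return build_hierarchy(bicliques)

    def test_root_with_one_child(self):
        cat = catalog_of(("A", "B"), ("C", "D"))
        h = self.hierarchy_chain({1}, {1, 2})
        _, edges = augment_root(h, 0, cat)
        assert edges == {("A", "B"), ("C", "D")}

    def test_root_without_descendants_unchanged(self):
        cat = catalog_of(("A", "B"))
        h = build_hierarchy([Biclique(frozenset({1}), frozenset({"P1", "P2"}))])
        _, edges = augment_root(h, 0, cat)
        assert edges == {("A", "B")}

    def test_depth_cutoff_at_two_levels(self):
        cat = catalog_of(("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"))
        h = self.hierarchy_chain({1}, {1, 2}, {1, 2, 3}, {1, 2, 3, 4})
        _, edges = augment_root(h, 0, cat)
        assert edges == {("A", "B"), ("C", "D"), ("E", "F")}  # d3's (G,H) excluded

    def test_non_root_rejected(self):
        cat = catalog_of(("A", "B"), ("C", "D"))
        h = self.hierarchy_chain({1}, {1, 2})
        with pytest.raises(KeyError):
            augment_root(h, 1, cat)

    def test_augmented_lcc_at_least_raw_lcc(self, rng):
        from pathkernel import (SynthSpec, build_catalog, build_incidence,
                                enumerate_maximal_bicliques, generate_collection)

        for seed in range(8):
            spec = SynthSpec(seed=seed)
            edge_lists, _ = generate_collection(spec)
            cat, pws = build_catalog(edge_lists)
            found = enumerate_maximal_bicliques(build_incidence(pws))
            h = build_hierarchy(found)
            raw = build_component_graphs(h, cat, augment_roots=False)
            aug = build_component_graphs(h, cat, augment_roots=True)
            for r in h.roots:
                assert aug[r].gene_edges >= raw[r].gene_edges
                assert len(aug[r].lcc_nodes) >= len(raw[r].lcc_nodes)


class TestColorNodes:
    def chain(self):
        cat = catalog_of(("A", "B"), ("B", "C"), ("C", "D"))
        h = build_hierarchy([
            Biclique(frozenset({1}), frozenset({"P1", "P2", "P3"})),
            Biclique(frozenset({1, 2}), frozenset({"P1", "P2"})),
        ])
        return cat, h

    def test_gene_in_root_and_child_colored_by_root(self):
        cat, h = self.chain()
        cgraphs = build_component_graphs(h, cat, augment_roots=False)
        colors = color_nodes(h, cgraphs)
        # A and B sit in both LCCs; the root (level 0) wins
        assert colors.assignment["A"][0] == 0
        assert colors.assignment["B"][0] == 0
        # C only appears in the child's LCC
        assert colors.assignment["C"][0] == 1

    def test_level_tie_broken_by_smallest_id(self):
        cat = catalog_of(("A", "B"), ("A", "C"))
        h = build_hierarchy([
            Biclique(frozenset({1}), frozenset({"P1", "P2"})),
            Biclique(frozenset({2}), frozenset({"P2", "P3"})),
        ])
        colors = color_nodes(h, build_component_graphs(h, cat))
        assert colors.assignment["A"][0] == 0  # in both level-0 LCCs

    def test_every_colored_gene_is_in_its_nodes_lcc(self, rng):
        cat, h = self.chain()
        cgraphs = build_component_graphs(h, cat)
        colors = color_nodes(h, cgraphs)
        for gene, (bid, _) in colors.assignment.items():
            assert gene in cgraphs[bid].lcc_nodes

    def test_color_index_cycles_palette(self):
        from pathkernel.components import PALETTE

        cat, h = self.chain()
        colors = color_nodes(h, build_component_graphs(h, cat))
        for bid, cidx in colors.assignment.values():
            assert cidx == bid % len(PALETTE)
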