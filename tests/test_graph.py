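"""Graph construction, coarsening and LINE/HARP embedding tests."""

import networkx as nx
import numpy as np
import pytest

from ddifuse.graph import (build_graph, coarsen, embed_or_fallback,
                           harp_embed, line2_embed, line2_objective,
                           NodeEmbedding, second_order_probabilities)


def _weighted(g):
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def _clique_separation(emb, groups):
    """Mean intra-group minus mean inter-group cosine of vertex vectors."""
    V = emb.vertex / np.linalg.norm(emb.vertex, axis=1, keepdims=True)
    cos = V @ V.T
    intra, inter = [], []
    for gi, ga in enumerate(groups):
        ia = [emb.index[n] for n in ga]
        intra += [cos[i, j] for i in ia for j in ia if i < j]
        for gb in groups[gi + 1:]:
            ib = [emb.index[n] for n in gb]
            inter += [cos[i, j] for i in ia for j in ib]
    return np.mean(intra) - np.mean(inter)


class TestBuildGraph:
    def test_duplicates_and_reverses_merge(self):
        g = build_graph([("A", "B"), ("B", "A"), ("A", "B")])
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 1.0

    def test_isolated_nodes_kept(self):
        g = build_graph([], node_universe={"A", "B"})
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 0

    def test_self_pair_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-interaction"):
            g = build_graph([("A", "A")])
        assert g.number_of_edges() == 0


class TestCoarsening:
    def test_path_levels_strictly_decrease(self):
        h = coarsen(_weighted(nx.path_graph(8)), threshold=2)
        sizes = [G.number_of_nodes() for G in h.levels]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] <= 2

    def test_small_graph_single_level(self):
        g = _weighted(nx.path_graph(3))
        h = coarsen(g, threshold=5)
        assert len(h) == 1 and h.levels[0] is g

    def test_star_collapsing_merges_leaves(self):
        h = coarsen(_weighted(nx.star_graph(6)), threshold=1)
        assert h.levels[1].number_of_nodes() < 7

    @pytest.mark.parametrize("maker", [
        lambda: nx.path_graph(12),
        lambda: nx.star_graph(9),
        lambda: nx.barbell_graph(6, 2),
    ])
    def test_invariants(self, maker):
        g = _weighted(maker())
        h = coarsen(g, threshold=2)
        sizes = [G.number_of_nodes() for G in h.levels]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        for k in range(len(h) - 1):
            fine, coarse, mapping = h.levels[k], h.levels[k + 1], h.maps[k]
            # surjectivity: every coarse node is some fine node's image
            assert set(mapping.values()) == set(coarse.nodes)
            assert set(mapping.keys()) == set(fine.nodes)
            # weight conservation: non-internal fine weight reappears summed
            expected = {}
            for u, v, data in fine.edges(data=True):
                mu, mv = mapping[u], mapping[v]
                if mu != mv:
                    key = (mu, mv) if str(mu) <= str(mv) else (mv, mu)
                    expected[key] = expected.get(key, 0.0) + data["weight"]
            got = {((u, v) if str(u) <= str(v) else (v, u)): d["weight"]
                   for u, v, d in coarse.edges(data=True)}
            assert got == pytest.approx(expected)
        # composed maps send every original node to exactly one coarsest node
        for node in g.nodes:
            assert h.project(node, len(h) - 1) in h.levels[-1].nodes


class TestLine2:
    def test_exact_softmax_normalises(self):
        g = _weighted(nx.cycle_graph(4))
        emb = line2_embed(g, dim=6, epochs=10, seed=0)
        p = second_order_probabilities(emb)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        # normalisation holds for any parameterisation, not just trained
        rnd = NodeEmbedding(nodes=emb.nodes,
                            vertex=np.random.default_rng(0).random((4, 6)),
                            context=np.random.default_rng(1).random((4, 6)))
        assert np.allclose(second_order_probabilities(rnd).sum(axis=1), 1.0,
                           atol=1e-6)

    def test_objective_decreases(self):
        g = _weighted(nx.gnm_random_graph(20, 40, seed=3))
        early = line2_embed(g, dim=16, epochs=5, seed=0)
        late = line2_embed(g, dim=16, epochs=400, seed=0)
        assert line2_objective(g, late) < line2_objective(g, early)

    def test_bridged_cliques_separate_all_seeds(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        _weighted(g)
        groups = [list(range(6)), list(range(6, 12))]
        for seed in range(10):
            emb = line2_embed(g, dim=16, epochs=1500, seed=seed)
            assert _clique_separation(emb, groups) > 0

    def test_edgeless_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from("AB")
        with pytest.raises(ValueError, match="no edges"):
            line2_embed(g)

    def test_deterministic_per_seed(self):
        g = _weighted(nx.cycle_graph(8))
        e1 = line2_embed(g, dim=4, epochs=20, seed=3)
        e2 = line2_embed(g, dim=4, epochs=20, seed=3)
        assert np.array_equal(e1.vertex, e2.vertex)


class TestHarp:
    def test_degenerate_hierarchy_equals_plain_line(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        _weighted(g)
        h = harp_embed(g, dim=8, threshold=100, epochs=30, seed=3)
        l = line2_embed(g, dim=8, epochs=30, seed=3)
        assert np.array_equal(h.vertex, l.vertex)
        assert np.array_equal(h.context, l.context)

    def test_all_nodes_covered(self):
        g = _weighted(nx.barbell_graph(8, 3))
        emb = harp_embed(g, dim=8, threshold=4, epochs=60, seed=0)
        assert set(emb.index) == set(g.nodes)
        assert np.all(np.isfinite(emb.vertex))

    def test_at_least_as_good_as_line_on_barbell(self):
        """Hierarchical initialisation beats a cold start at equal budget."""
        g = _weighted(nx.barbell_graph(8, 3))
        groups = [list(range(8)), list(range(11, 19))]
        hs, ls = [], []
        for seed in range(10):
            hs.append(_clique_separation(
                harp_embed(g, dim=16, threshold=6, epochs=100, seed=seed),
                groups))
            ls.append(_clique_separation(
                line2_embed(g, dim=16, epochs=100, seed=seed), groups))
        assert np.median(hs) >= np.median(ls)

    @staticmethod
    def _cycle_stats(emb, g):
        """Distance statistics of a cycle embedding: overall mean and the
        adjacent-to-overall ratio."""
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(emb.vertex))
        n = len(emb.nodes)
        adj = np.mean([D[emb.index[u], emb.index[v]] for u, v in g.edges])
        overall = D[np.triu_indices(n, 1)].mean()
        return overall, adj / overall

    def test_seed_stability_on_vertex_transitive_graph(self):
        """On a cycle the pairwise-distance statistics are seed-stable."""
        g = _weighted(nx.cycle_graph(12))
        overall, ratio = [], []
        for seed in range(10):
            o, r = self._cycle_stats(
                line2_embed(g, dim=8, epochs=1000, seed=seed), g)
            overall.append(o)
            ratio.append(r)
        for stat in (np.array(overall), np.array(ratio)):
            assert stat.std() / abs(stat.mean()) < 0.2

    def test_relabeling_invariance_in_distribution(self):
        g = _weighted(nx.cycle_graph(12))
        relabel = {i: f"n{(i * 5) % 12}" for i in range(12)}
        g2 = nx.relabel_nodes(g, relabel)
        o1, r1 = self._cycle_stats(line2_embed(g, dim=8, epochs=1000,
                                               seed=1), g)
        o2, r2 = self._cycle_stats(line2_embed(g2, dim=8, epochs=1000,
                                               seed=1), g2)
        assert abs(o1 - o2) < 0.1 * max(o1, o2)
        assert abs(r1 - r2) < 0.1 * max(r1, r2)


class TestFallback:
    def setup_method(self):
        self.g = build_graph([("A", "B"), ("B", "C")],
                             node_universe={"A", "B", "C", "D", "E"})
        self.emb = line2_embed(self.g.subgraph(["A", "B", "C"]).copy(),
                               dim=8, epochs=50, seed=0)

    def test_embedded_node_own_vector(self):
        v = embed_or_fallback("A", self.g, self.emb)
        assert np.array_equal(v, self.emb.vector("A"))

    def test_unembedded_with_neighbor_copies_bitwise(self):
        g = build_graph([("A", "B"), ("B", "C"), ("D", "B"), ("D", "A")],
                        node_universe={"A", "B", "C", "D"})
        # D absent from the embedding but has neighbours A and B;
        # lexicographically smallest embedded neighbour is A
        v = embed_or_fallback("D", g, self.emb)
        assert np.array_equal(v, self.emb.vector("A"))

    def test_isolated_node_zero_vector(self):
        v = embed_or_fallback("E", self.g, self.emb)
        assert v.shape == (8,) and np.all(v == 0)
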