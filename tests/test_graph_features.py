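"""Graph metrics against analytic cases and exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

from conftest import graph_from_adjacency, graph_from_edges
from oracles import (
    bf_assortativity,
    bf_best_partition,
    bf_betweenness,
    bf_clustering,
    bf_cpl_efficiency,
    bf_eigenvector,
    bf_local_efficiency,
    bf_participation,
    bf_transitivity,
    bf_within_module_z,
    random_binary_graph,
)
from signedfc import graph_features as gf
from signedfc.connectivity import BinaryGraph


def complete_graph(n):
    return graph_from_edges(n, itertools.combinations(range(n), 2))


def path_graph(n):
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n):
    return graph_from_edges(n, [(0, i) for i in range(1, n)])


class TestAnalyticCases:
    def test_degree_of_star(self):
        d = gf.degree(star_graph(5))
        assert d[0] == 4 and set(d[1:]) == {1}

    def test_degree_of_empty_graph(self):
        assert np.all(gf.degree(graph_from_edges(4, [])) == 0)

    def test_clustering_and_transitivity_of_triangle(self):
        k3 = complete_graph(3)
        assert np.allclose(gf.clustering_coefficient(k3), 1.0)
        assert gf.transitivity(k3) == pytest.approx(1.0)

    def test_clustering_and_transitivity_of_path(self):
        p4 = path_graph(4)
        assert np.allclose(gf.clustering_coefficient(p4), 0.0)
        assert gf.transitivity(p4) == 0.0

    def test_path_metrics_on_p3(self):
        cpl, eff = gf.shortest_path_metrics(path_graph(3))
        assert cpl == pytest.approx(4 / 3)
        assert eff == pytest.approx(5 / 6)

    def test_path_metrics_on_complete_graph(self):
        cpl, eff = gf.shortest_path_metrics(complete_graph(4))
        assert cpl == pytest.approx(1.0) and eff == pytest.approx(1.0)

    def test_path_metrics_on_disconnected_pairs(self):
        """Two disjoint edges: CPL averages the finite pairs only;
        efficiency counts the unreachable pairs as zero."""
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        cpl, eff = gf.shortest_path_metrics(g)
        assert cpl == pytest.approx(1.0)
        assert eff == pytest.approx(4 / 12)

    def test_single_node_graph_rejected(self):
        with pytest.raises(ValueError):
            gf.shortest_path_metrics(graph_from_edges(1, []))

    def test_local_efficiency_extremes(self):
        assert np.allclose(gf.local_efficiency(complete_graph(4)), 1.0)
        assert np.allclose(gf.local_efficiency(star_graph(6)), 0.0)

    def test_betweenness_of_path_and_star(self):
        assert gf.betweenness_centrality(path_graph(3)).tolist() == [0.0, 1.0, 0.0]
        n = 7
        bc = gf.betweenness_centrality(star_graph(n))
        assert bc[0] == pytest.approx((n - 1) * (n - 2) / 2)
        assert np.allclose(bc[1:], 0.0)

    def test_eigenvector_centrality_uniform_on_cycle(self):
        c5 = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        assert np.allclose(gf.eigenvector_centrality(c5), 1 / np.sqrt(5))

    def test_eigenvector_centrality_zero_off_giant_component(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        v = gf.eigenvector_centrality(g)
        assert v[3] == 0.0
        assert np.allclose(v[:3], v[0]) and v[0] > 0

    def test_assortativity_of_star_is_minus_one(self):
        assert gf.assortativity(star_graph(6)) == pytest.approx(-1.0)

    def test_assortativity_sentinel_on_regular_graph(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(UserWarning, match="degenerate"):
            assert gf.assortativity(g) == 0.0

    def test_assortativity_requires_an_edge(self):
        with pytest.raises(ValueError):
            gf.assortativity(graph_from_edges(3, []))


class TestCommunities:
    def test_two_cliques_recovered_at_optimal_modularity(self):
        edges = list(itertools.combinations(range(4), 2)) + list(
            itertools.combinations(range(4, 8), 2)
        )
        g = graph_from_edges(8, edges)
        part = gf.detect_communities(g, seed=1)
        labels = np.asarray(part.assignment)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert part.modularity_q == pytest.approx(0.5)
        # exhaustive search over all partitions confirms this is the optimum
        _, best_q = bf_best_partition(g.adjacency())
        assert part.modularity_q == pytest.approx(best_q)

    def test_complete_graph_has_zero_modularity(self):
        part = gf.detect_communities(complete_graph(5), seed=0)
        assert part.modularity_q == pytest.approx(0.0)
        assert part.n_modules == 1

    def test_clique_ring_recovers_four_modules(self):
        cliques = [list(range(4 * i, 4 * i + 4)) for i in range(4)]
        edges = [e for c in cliques for e in itertools.combinations(c, 2)]
        edges += [(3, 4), (7, 8), (11, 12), (15, 0)]  # single bridges
        g = graph_from_edges(16, edges)
        part = gf.detect_communities(g, seed=2)
        assert part.n_modules == 4
        for c in cliques:
            assert len({part.assignment[v] for v in c}) == 1

    def test_isolated_nodes_get_singleton_modules(self):
        g = graph_from_edges(4, [(0, 1)])
        part = gf.detect_communities(g, seed=0)
        assert part.assignment[2] != part.assignment[3]


class TestParticipationAndZscore:
    def test_all_edges_within_own_module_gives_zero(self):
        g = complete_graph(4)
        part = gf.CommunityPartition(assignment=(0, 0, 0, 0), modularity_q=0.0)
        assert np.allclose(gf.participation_coefficient(g, part), 0.0)

    def test_even_split_across_two_modules_gives_half(self):
        g = graph_from_edges(3, [(0, 1), (0, 2)])
        part = gf.CommunityPartition(assignment=(0, 0, 1), modularity_q=0.0)
        assert gf.participation_coefficient(g, part)[0] == pytest.approx(0.5)

    def test_zscore_of_clique_module_is_zero(self):
        g = complete_graph(4)
        part = gf.CommunityPartition(assignment=(0, 0, 0, 0), modularity_q=0.0)
        assert np.allclose(gf.within_module_zscore(g, part), 0.0)

    def test_zscore_hand_example_population_sd(self):
        """Within-degrees {1, 1, 4} in one module -> z = {-1, -1, 2}/sqrt(2)."""
        # node 2 connects to 0, 1 and to two extra nodes of its own module
        edges = [(0, 2), (1, 2), (2, 3), (2, 4), (3, 4)]
        g = graph_from_edges(5, edges)
        part = gf.CommunityPartition(assignment=(0, 0, 1, 1, 1), modularity_q=0.0)
        z = gf.within_module_zscore(g, part)
        # module 1 within-degrees are {2, 2, 2} -> sd 0 sentinel
        assert np.allclose(z[2:], 0.0)
        # now an asymmetric module
        g2 = graph_from_edges(3, [(0, 1)])
        part2 = gf.CommunityPartition(assignment=(0, 0, 0), modularity_q=0.0)
        z2 = gf.within_module_zscore(g2, part2)
        mu, sd = np.mean([1, 1, 0]), np.std([1, 1, 0])
        assert z2[0] == pytest.approx((1 - mu) / sd)
        assert z2[2] == pytest.approx((0 - mu) / sd)

    def test_partition_must_cover_all_nodes(self):
        g = complete_graph(3)
        bad = gf.CommunityPartition(assignment=(0, 0), modularity_q=0.0)
        with pytest.raises(ValueError):
            gf.participation_coefficient(g, bad)


class TestBruteForceEquivalence:
    """Exhaustive oracles on random small graphs (the core correctness net)."""

    def test_all_metrics_match_oracles_on_random_graphs(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 11))
            a = random_binary_graph(n, float(rng.uniform(0.2, 0.8)), rng)
            g = graph_from_adjacency(a)
            assert np.allclose(gf.degree(g), a.sum(axis=1), atol=1e-10)
            assert np.allclose(gf.clustering_coefficient(g), bf_clustering(a), atol=1e-10)
            assert gf.transitivity(g) == pytest.approx(bf_transitivity(a), abs=1e-10)
            cpl, eff = gf.shortest_path_metrics(g)
            bf_cpl, bf_eff = bf_cpl_efficiency(a)
            assert cpl == pytest.approx(bf_cpl, abs=1e-10)
            assert eff == pytest.approx(bf_eff, abs=1e-10)
            assert np.allclose(gf.local_efficiency(g), bf_local_efficiency(a), atol=1e-10)
            assert np.allclose(
                gf.betweenness_centrality(g), bf_betweenness(a), atol=1e-9
            )
            modules = np.asarray(rng.integers(0, 3, size=n))
            part = gf.CommunityPartition(tuple(int(m) for m in modules), 0.0)
            assert np.allclose(
                gf.participation_coefficient(g, part), bf_participation(a, modules),
                atol=1e-10,
            )
            assert np.allclose(
                gf.within_module_zscore(g, part), bf_within_module_z(a, modules),
                atol=1e-10,
            )
            if a.sum() > 0:
                r_bf = bf_assortativity(a)
                r = gf.assortativity(g) if np.isfinite(r_bf) else None
                if r is not None:
                    assert r == pytest.approx(r_bf, abs=1e-10)

    def test_eigenvector_matches_power_iteration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            a = random_binary_graph(n, 0.5, rng)
            g = graph_from_adjacency(a)
            assert np.allclose(
                gf.eigenvector_centrality(g), bf_eigenvector(a), atol=1e-8
            )


class TestInvariants:
    def test_node_metrics_permute_with_relabelling(self, rng):
        n = 9
        a = random_binary_graph(n, 0.4, rng)
        perm = rng.permutation(n)
        ap = a[np.ix_(perm, perm)]
        g, gp = graph_from_adjacency(a), graph_from_adjacency(ap)
        for fn in (gf.degree, gf.clustering_coefficient, gf.local_efficiency,
                   gf.betweenness_centrality):
            assert np.allclose(fn(g)[perm], fn(gp), atol=1e-10)

    def test_adding_an_edge_never_hurts_efficiency(self, rng):
        for _ in range(10):
            a = random_binary_graph(8, 0.3, rng)
            g = graph_from_adjacency(a)
            _, eff = gf.shortest_path_metrics(g)
            free = [(i, j) for i in range(8) for j in range(i + 1, 8) if not a[i, j]]
            if not free:
                continue
            i, j = free[int(rng.integers(len(free)))]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = 1
            _, eff2 = gf.shortest_path_metrics(graph_from_adjacency(a2))
            assert eff2 >= eff - 1e-12
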