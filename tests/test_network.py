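import itertools
from collections import Counter, deque

import networkx as nx
import numpy as np
import pytest

from grffl.datatypes import ContingencyTable, ValidationError
from grffl.network import (
    chi_square_yates,
    edge_betweenness,
    girvan_newman,
    hub_edge_fraction,
    module_composition_test,
    topology_report,
)
from tests.conftest import random_graph


def brute_edge_betweenness(g: nx.Graph) -> dict:
    """Oracle: enumerate all shortest paths per node pair with BFS + DFS."""
    eb = {tuple(sorted(e, key=str)): 0.0 for e in g.edges()}
    nodes = list(g.nodes())
    for s, t in itertools.combinations(nodes, 2):
        # collect all shortest s-t paths
        dist = {s: 0}
        parents = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        if t not in dist:
            continue
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append(acc)
                return
            for p in parents[v]:
                walk(p, acc + [(p, v)])

        walk(t, [])
        for path in paths:
            for u, v in path:
                eb[tuple(sorted((u, v), key=str))] += 1.0 / len(paths)
    return eb


class TestEdgeBetweenness:
    def test_triangle_all_ones(self):
        g = nx.cycle_graph(3)
        assert all(b == pytest.approx(1.0) for b in edge_betweenness(g).values())

    def test_path_edges(self):
        g = nx.path_graph(["a", "b", "c"])
        eb = edge_betweenness(g)
        assert eb[("a", "b")] == pytest.approx(2.0)
        assert eb[("b", "c")] == pytest.approx(2.0)

    def test_matches_bruteforce_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            g = random_graph(rng, n_max=6)
            eb = edge_betweenness(g)
            oracle = brute_edge_betweenness(g)
            assert set(eb) == set(oracle)
            for e in eb:
                assert eb[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_total_betweenness_equals_path_length_sum(self):
        # every unordered connected pair contributes its path length in total
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = random_graph(rng, n_max=6)
            total = sum(edge_betweenness(g).values())
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            expected = sum(
                lengths[s][t]
                for s, t in itertools.combinations(g.nodes(), 2)
                if t in lengths[s]
            )
            assert total == pytest.approx(expected)


class TestGirvanNewman:
    def test_bridge_removed_first(self, bridge_of_triangles):
        part = girvan_newman(bridge_of_triangles, target_modules=2)
        (edge, betweenness) = part.removal_history[0]
        assert edge == ("c", "d")
        assert betweenness == pytest.approx(9.0)  # 3x3 crossing pairs
        modules = part.modules()
        assert sorted(sorted(m) for m in modules.values()) == [
            ["a", "b", "c"], ["d", "e", "f"]]

    def test_disconnected_identity(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        part = girvan_newman(g, target_modules=2)
        assert part.removal_history == []
        assert part.n_modules == 2

    def test_auto_mode_finds_triangles(self, bridge_of_triangles):
        part = girvan_newman(bridge_of_triangles, target_modules="auto")
        assert part.n_modules == 2
        assert part.membership["a"] == part.membership["b"] == part.membership["c"]
        assert part.membership["d"] == part.membership["e"] == part.membership["f"]

    def test_target_above_n_rejected(self, bridge_of_triangles):
        with pytest.raises(ValidationError):
            girvan_newman(bridge_of_triangles, target_modules=7)

    def test_planted_partition_recovery_single_seed(self):
        from sklearn.metrics import adjusted_rand_score

        from grffl.synthetic import PlantedGraphSpec, gen_planted_network

        g, truth = gen_planted_network(
            PlantedGraphSpec(sizes=(20, 20, 20), p_in=0.3, p_out=0.02, seed=0))
        part = girvan_newman(g, target_modules=3)
        nodes = list(g.nodes())
        ari = adjusted_rand_score([truth[v] for v in nodes],
                                  [part.membership[v] for v in nodes])
        assert ari >= 0.9

    def test_removal_history_deterministic(self, bridge_of_triangles):
        h1 = girvan_newman(bridge_of_triangles, "auto").removal_history
        h2 = girvan_newman(bridge_of_triangles, "auto").removal_history
        assert h1 == h2


def brute_topology(g: nx.Graph):
    """Oracle: naive re-implementation of every topology metric."""
    nodes = list(g.nodes())
    n = len(nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    deg = {v: len(adj[v]) for v in nodes}
    density = sum(deg.values()) / (n * (n - 1))
    clustering = {}
    for v in nodes:
        k = deg[v]
        if k < 2:
            clustering[v] = 0.0
        else:
            links = sum(1 for a, b in itertools.combinations(adj[v], 2)
                        if b in adj[a])
            clustering[v] = 2.0 * links / (k * (k - 1))
    degs = np.array([deg[v] for v in nodes], float)
    het = float(np.sqrt(np.mean((degs - degs.mean()) ** 2)) / degs.mean()) \
        if degs.mean() > 0 else 0.0
    nbh = {v: (sum(deg[u] for u in adj[v]) / deg[v] if deg[v] else 0.0)
           for v in nodes}
    hist = Counter(len(adj[u] & adj[v])
                   for u, v in itertools.combinations(nodes, 2))
    return density, clustering, het, nbh, dict(hist)


class TestTopology:
    def test_triangle(self):
        rep = topology_report(nx.complete_graph(3))
        assert rep.density == pytest.approx(1.0)
        assert rep.avg_clustering == pytest.approx(1.0)
        assert rep.heterogeneity == pytest.approx(0.0)

    def test_star_hand_values(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        rep = topology_report(g)
        # degrees (3,1,1,1): population sd 0.8660, mean 1.5
        assert rep.heterogeneity == pytest.approx(0.8660254 / 1.5, abs=1e-6)
        assert rep.neighborhood_connectivity[0] == pytest.approx(1.0)
        assert rep.neighborhood_connectivity[1] == pytest.approx(3.0)

    def test_matches_bruteforce_suite(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            g = random_graph(rng, n_max=8)
            rep = topology_report(g)
            density, clustering, het, nbh, hist = brute_topology(g)
            assert rep.density == pytest.approx(density)
            assert rep.heterogeneity == pytest.approx(het)
            for v in g.nodes():
                assert rep.clustering[v] == pytest.approx(clustering[v])
                assert rep.neighborhood_connectivity[v] == pytest.approx(nbh[v])
            assert rep.shared_neighbor_histogram == hist

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValidationError):
            topology_report(g)


class TestHubEdgeFraction:
    def test_star_center(self):
        assert hub_edge_fraction(nx.star_graph(5), 1) == pytest.approx(1.0)

    def test_triangle_single_hub(self):
        assert hub_edge_fraction(nx.complete_graph(3), 1) == pytest.approx(2 / 3)

    def test_monotone_in_top_n(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, n_max=8)
        fracs = [hub_edge_fraction(g, k) for k in range(g.number_of_nodes() + 1)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_degree_mode_counts_hub_hub_twice(self):
        g = nx.complete_graph(4)
        assert hub_edge_fraction(g, 2, mode="incident") == pytest.approx(5 / 6)
        assert hub_edge_fraction(g, 2, mode="degree") == pytest.approx(6 / 12)


class TestChiSquareYates:
    def test_module_go_worked_example(self):
        # 22/425 vs 32/285 gene-expression-related GO categories
        r = chi_square_yates(ContingencyTable(22, 403, 32, 253))
        assert r.statistic == pytest.approx(8.05, abs=0.005)
        assert r.p_value == pytest.approx(0.00455, abs=5e-5)

    def test_independence_gives_zero(self):
        r = chi_square_yates(ContingencyTable(10, 10, 10, 10))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_example(self):
        r = chi_square_yates(ContingencyTable(20, 80, 40, 60))
        assert r.statistic == pytest.approx(8.595238, abs=1e-5)

    def test_symmetries_and_scaling(self):
        base = chi_square_yates(ContingencyTable(20, 80, 40, 60)).statistic
        transpose = chi_square_yates(ContingencyTable(20, 40, 80, 60)).statistic
        rowswap = chi_square_yates(ContingencyTable(40, 60, 20, 80)).statistic
        scaled = chi_square_yates(ContingencyTable(200, 800, 400, 600)).statistic
        assert transpose == pytest.approx(base)
        assert rowswap == pytest.approx(base)
        assert scaled > base

    def test_matches_scipy_correction(self):
        from scipy.stats import chi2_contingency

        t = ContingencyTable(22, 403, 32, 253)
        ours = chi_square_yates(t)
        ref = chi2_contingency(t.as_array(), correction=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_yates(ContingencyTable(0, 0, 5, 5))


class TestModuleComposition:
    def _aligned_partition(self, size=25):
        from grffl.network import CommunityPartition

        membership = {f"a{i}": 0 for i in range(size)}
        membership.update({f"b{i}": 1 for i in range(size)})
        return CommunityPartition(membership, 2)

    def test_perfectly_aligned_class_significant(self):
        part = self._aligned_partition()
        node_class = {v: v.startswith("a") for v in part.membership}
        rows = module_composition_test(part, node_class)
        assert all(r["p_value"] < 1e-3 for r in rows if not r["skipped"])

    def test_marginals_sum_to_n(self):
        part = self._aligned_partition(10)
        node_class = {v: v.endswith(("0", "1")) for v in part.membership}
        rows = module_composition_test(part, node_class)
        for r in rows:
            assert r["size"] + (len(part.membership) - r["size"]) == 20

    def test_random_class_null_calibration(self):
        from grffl.network import CommunityPartition

        false_pos = 0
        trials = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            membership = {f"n{i}": int(i // 20) for i in range(60)}
            part = CommunityPartition(membership, 3)
            node_class = {v: bool(rng.random() < 0.4) for v in membership}
            for r in module_composition_test(part, node_class):
                if not r["skipped"]:
                    trials += 1
                    false_pos += r["p_value"] < 0.05
        assert false_pos / trials <= 0.1
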