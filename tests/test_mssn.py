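"""Shortest-path search, background sampling and the Welch path statistic."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps
from scipy.sparse.csgraph import floyd_warshall

from drivernet import mssn
from drivernet.io import PPINetwork


def net_from_edges(edges):
    g = nx.Graph()
    for e in edges:
        a, b, *w = e
        g.add_edge(a, b, weight=w[0] if w else 1.0)
    return PPINetwork(graph=g)


class TestShortestDistances:
    def test_path_graph(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        assert mssn.shortest_distances(net, "a", {"c"})["c"] == 2

    def test_triangle_prefers_two_hop_route(self):
        # direct edge a-c costs 3; a-b-c costs 2; exhaustive enumeration
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)])
        all_paths = nx.all_simple_paths(net.graph, "a", "c")
        best = min(
            sum(net.graph[u][v]["weight"] for u, v in zip(p, p[1:])) for p in all_paths
        )
        assert mssn.shortest_distances(net, "a", {"c"})["c"] == best == 2.0

    def test_unreachable_flagged_not_error(self):
        net = net_from_edges([("a", "b"), ("x", "y")])
        assert math.isinf(mssn.shortest_distances(net, "a", {"y"})["y"])

    def test_missing_source_names_gene(self):
        net = net_from_edges([("a", "b")])
        with pytest.raises(ValueError, match="zzz"):
            mssn.shortest_distances(net, "zzz", {"a"})

    def test_agrees_with_floyd_warshall_on_random_graphs(self, rng):
        # dyadic weights make both algorithms' path sums exact in float64
        for _ in range(20):
            n = int(rng.integers(5, 50))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                g = nx.compose(g, nx.path_graph(n))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.integers(1, 64)) / 16.0
            net = PPINetwork(graph=nx.relabel_nodes(g, str))
            nodes = sorted(net.graph.nodes)
            adj = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight")
            fw = floyd_warshall(adj, directed=False)
            src = nodes[int(rng.integers(len(nodes)))]
            d = mssn.shortest_distances(net, src, set(nodes))
            i = nodes.index(src)
            for j, v in enumerate(nodes):
                assert d[v] == fw[i, j]


FIXTURE = [
    ("s", "a"), ("a", "t1"),               # 2-hop target via a
    ("s", "d"), ("d", "t1"),               # equal-cost alternative via d
    ("s", "b"), ("b", "c"), ("c", "t2"),   # 3-hop target
    ("x", "y"),                            # separate component
]


class TestBuildMssn:
    def test_star_of_adjacent_targets(self):
        net = net_from_edges([("s", "t1"), ("s", "t2"), ("s", "t3")])
        sub = mssn.build_mssn(net, "s", {"t1", "t2", "t3"}, "up")
        assert sorted(sub.distances.values()) == [1, 1, 1]
        assert sub.nodes == {"s", "t1", "t2", "t3"}

    def test_hand_traced_fixture(self):
        net = net_from_edges(FIXTURE)
        sub = mssn.build_mssn(net, "s", {"t1", "t2"}, "up")
        assert sorted(sub.distances.values()) == [2, 3]
        # lexicographic tie-break keeps the path via 'a', not 'd'
        assert sub.nodes == {"s", "a", "t1", "b", "c", "t2"}
        assert frozenset(("s", "a")) in sub.edges
        assert frozenset(("s", "d")) not in sub.edges

    def test_unreachable_target_counted(self):
        net = net_from_edges(FIXTURE)
        sub = mssn.build_mssn(net, "s", {"t1", "y"}, "up")
        assert sub.unreachable == {"y"}
        assert list(sub.distances) == ["t1"]

    def test_empty_intersection_names_direction(self):
        net = net_from_edges(FIXTURE)
        with pytest.raises(ValueError, match="down"):
            mssn.build_mssn(net, "s", {"nope"}, "down")

    def test_seed_excluded_from_targets(self):
        net = net_from_edges([("s", "t1")])
        sub = mssn.build_mssn(net, "s", {"s", "t1"}, "up")
        assert set(sub.distances) == {"t1"}


class TestBackground:
    def test_complete_graph_all_distances_one(self):
        net = net_from_edges([(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)])
        bg = mssn.background_distances(net, n_targets=2, n_replicates=10, rng=0)
        assert np.all(bg.pooled == 1.0)

    def test_reproducible_from_seed(self):
        net = net_from_edges([(f"n{i}", f"n{i+1}") for i in range(20)])
        a = mssn.background_distances(net, 3, 50, rng=42)
        b = mssn.background_distances(net, 3, 50, rng=42)
        assert np.array_equal(a.pooled, b.pooled)
        assert np.array_equal(a.replicate_means, b.replicate_means)

    def test_path_graph_mean_matches_exact_expectation(self):
        # P5: average distance over ordered pairs = 2.0 exactly
        net = net_from_edges([(f"n{i}", f"n{i+1}") for i in range(4)])
        nodes = sorted(net.graph.nodes)
        exact = np.mean([
            nx.shortest_path_length(net.graph, u, v)
            for u in nodes for v in nodes if u != v
        ])
        bg = mssn.background_distances(net, 1, 10_000, rng=1)
        se = bg.pooled.std(ddof=1) / math.sqrt(bg.pooled.size)
        assert abs(bg.pooled.mean() - exact) < 3 * se

    def test_too_few_replicates_rejected(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        with pytest.raises(ValueError, match="n_replicates"):
            mssn.background_distances(net, 1, 1, rng=0)


class TestWelchT:
    def test_identical_samples_give_zero(self):
        st = mssn.welch_t([1, 2, 3], [1, 2, 3])
        assert st.t == pytest.approx(0.0)

    def test_hand_case_sign_convention(self):
        # shorter subnetwork paths -> positive t
        st = mssn.welch_t([4, 5, 6], [1, 2, 3])
        assert st.t == pytest.approx(3.0 / math.sqrt(2.0 / 3.0))
        assert st.t == pytest.approx(3.674, abs=1e-3)

    def test_swap_negates(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 7)
        assert mssn.welch_t(a, b).t == pytest.approx(-mssn.welch_t(b, a).t)

    def test_matches_scipy_reference(self, rng):
        for _ in range(200):
            a = rng.normal(0, 1, int(rng.integers(3, 30)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 30)))
            ours = mssn.welch_t(a, b).t
            ref = sps.ttest_ind(a, b, equal_var=False).statistic
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_fields_satisfy_definition(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 8)
        st = mssn.welch_t(a, b)
        lhs = st.t
        rhs = (st.mean_background - st.mean_observed) / math.sqrt(
            st.var_background / st.n_background + st.var_observed / st.n_observed
        )
        assert lhs == pytest.approx(rhs)
        assert st.var_background == pytest.approx(np.var(a, ddof=1))

    def test_empty_observed_sample_flagged(self):
        st = mssn.welch_t([1, 2, 3], [])
        assert st.degenerate and math.isnan(st.t)

    def test_empirical_p_is_fraction_of_replicate_means_below(self):
        st = mssn.welch_t([3, 3, 4, 4], [2.0, 2.0], replicate_means=[1.5, 2.5, 3.5, 4.0])
        assert st.empirical_p == pytest.approx(0.25)


class TestEvaluateSeed:
    def test_planted_seed_scores_high(self):
        from drivernet.synthetic import make_toy_study
        from drivernet.dge import call_de_genes, two_class_ttest

        study = make_toy_study(3)
        de = call_de_genes(two_class_ttest(study.expression))
        seed = study.truth.driver_seeds[0]
        res = mssn.evaluate_seed(study.network, seed, {"up": de.up, "down": de.down},
                                 n_replicates=200, rng=0)
        for direction, (sub, st) in res.items():
            assert st.t > 0
            assert st.empirical_p < 0.05
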