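"""Graph metrics, null models, bootstrap, and statistical tests vs oracles."""

import itertools

import numpy as np
import pytest

from fluencynet.errors import (
    ConfigurationError,
    DegenerateDistributionError,
    UndefinedMetricError,
)
from fluencynet.estimate import SemanticNetwork, cosine_similarity, tmfg_filter
from fluencynet.metrics import (
    MetricDistribution,
    aspl,
    bootstrap_partial_networks,
    compare_distributions,
    compare_local_metrics,
    er_baseline,
    global_cc,
    local_metrics,
    modularity,
    paired_t,
    z_test,
)
from fluencynet.preprocess import ResponseMatrix

from tests.conftest import random_binary_matrix, random_similarity


def net_from_edges(n, edges, weights=None):
    adj = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        adj[i, j] = adj[j, i] = w
        mask[i, j] = mask[j, i] = True
    return SemanticNetwork(tuple(f"n{i}" for i in range(n)), adj, mask)


def floyd_warshall_aspl(net):
    n = net.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for i, j, _ in net.edges():
        d[i, j] = d[j, i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    vals = d[np.triu_indices(n, 1)]
    return vals[np.isfinite(vals)].mean()


def exhaustive_modularity(net):
    """Best weighted modularity over every partition of <= 8 nodes."""
    import networkx as nx

    g = net.to_networkx()
    nodes = list(g.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
        best = max(best, q)
    return best


def zhang_brute_force(net):
    W = net.adjacency / net.adjacency.max()
    n = net.n_nodes
    out = np.zeros(n)
    for i in range(n):
        num = sum(
            W[i, j] * W[j, k] * W[k, i]
            for j in range(n)
            for k in range(n)
            if j != k and j != i and k != i
        )
        s = sum(W[i, j] for j in range(n) if j != i)
        s2 = sum(W[i, j] ** 2 for j in range(n) if j != i)
        denom = s**2 - s2
        out[i] = num / denom if denom > 1e-15 else 0.0
    return out


class TestASPL:
    def test_complete_graph_k4(self):
        net = net_from_edges(4, list(itertools.combinations(range(4), 2)))
        assert aspl(net) == pytest.approx(1.0)

    def test_path_of_three(self):
        net = net_from_edges(3, [(0, 1), (1, 2)])
        assert aspl(net) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("n", [6, 10, 15])
    def test_matches_floyd_warshall_on_tmfg(self, n):
        rng = np.random.default_rng(n)
        net = tmfg_filter(random_similarity(n, rng))
        assert aspl(net) == pytest.approx(floyd_warshall_aspl(net))

    def test_disconnected_averages_connected_pairs(self):
        net = net_from_edges(4, [(0, 1), (2, 3)])
        assert aspl(net) == pytest.approx(1.0)

    def test_edgeless_raises(self):
        net = SemanticNetwork(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(UndefinedMetricError):
            aspl(net)

    def test_adding_edge_never_increases_aspl(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = tmfg_filter(random_similarity(10, rng))
            non_edges = [
                (i, j)
                for i, j in itertools.combinations(range(10), 2)
                if not net.mask[i, j]
            ]
            i, j = non_edges[rng.integers(len(non_edges))]
            adj = net.adjacency.copy()
            mask = net.mask.copy()
            adj[i, j] = adj[j, i] = 0.5
            mask[i, j] = mask[j, i] = True
            bigger = SemanticNetwork(net.words, adj, mask)
            assert aspl(bigger) <= aspl(net) + 1e-12


class TestGlobalCC:
    def test_triangle_is_one(self, triangle_network):
        assert global_cc(triangle_network) == pytest.approx(1.0)

    def test_star_is_zero(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert global_cc(net) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_triad_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = tmfg_filter(random_similarity(9, rng))
        A = net.backbone()
        n = 9
        locals_ = []
        for i in range(n):
            nb = [j for j in range(n) if A[i, j]]
            if len(nb) < 2:
                locals_.append(0.0)
                continue
            closed = sum(
                A[u, v] for u, v in itertools.combinations(nb, 2)
            )
            locals_.append(closed / (len(nb) * (len(nb) - 1) / 2))
        assert global_cc(net) == pytest.approx(np.mean(locals_))


class TestModularity:
    def test_single_clique_zero(self):
        net = net_from_edges(4, list(itertools.combinations(range(4), 2)))
        q, part = modularity(net, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(part) == 1

    def test_two_disjoint_triangles(self):
        net = net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q, part = modularity(net, seed=0)
        assert q == pytest.approx(0.5)
        assert len(part) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_louvain_near_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        edges = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if rng.random() < 0.45
        ]
        if not edges:
            pytest.skip("empty draw")
        weights = rng.uniform(0.1, 1.0, len(edges))
        net = net_from_edges(n, edges, weights)
        q, _ = modularity(net, seed=seed, restarts=10)
        q_star = exhaustive_modularity(net)
        assert q >= q_star - 0.02

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        net = tmfg_filter(random_similarity(20, rng))
        q1, p1 = modularity(net, seed=11)
        q2, p2 = modularity(net, seed=11)
        assert q1 == q2 and p1 == p2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(17)
        net = tmfg_filter(random_similarity(12, rng))
        perm = rng.permutation(12)
        net_p = SemanticNetwork(
            tuple(net.words[i] for i in perm),
            net.adjacency[np.ix_(perm, perm)],
            net.mask[np.ix_(perm, perm)],
        )
        assert aspl(net_p) == pytest.approx(aspl(net))
        assert global_cc(net_p) == pytest.approx(global_cc(net))
        q, _ = modularity(net, seed=3)
        qp, _ = modularity(net_p, seed=3)
        assert qp == pytest.approx(q, abs=0.03)


class TestLocalMetrics:
    def test_equal_weight_triangle(self, triangle_network):
        loc = local_metrics(triangle_network)
        np.testing.assert_allclose(loc.local_cc, 1.0)
        np.testing.assert_allclose(loc.strength, 1.0)

    def test_star_center_zero_cc(self):
        net = net_from_edges(4, [(0, 1), (0, 2), (0, 3)], [0.5, 0.7, 0.9])
        loc = local_metrics(net)
        assert loc.local_cc[0] == 0.0
        assert loc.strength[0] == pytest.approx(2.1)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_brute_force_triple_sum(self, seed):
        rng = np.random.default_rng(seed)
        net = tmfg_filter(random_similarity(8, rng))
        loc = local_metrics(net)
        np.testing.assert_allclose(loc.local_cc, zhang_brute_force(net), atol=1e-12)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(33)
        net = tmfg_filter(random_similarity(25, rng))
        loc = local_metrics(net)
        assert np.all(loc.local_cc >= 0) and np.all(loc.local_cc <= 1 + 1e-12)


class TestERBaseline:
    def test_p_one_forces_complete_graphs(self):
        dists = er_baseline(6, 15, reps=5, seed=0)
        np.testing.assert_allclose(dists["aspl"].values, 1.0)
        np.testing.assert_allclose(dists["cc"].values, 1.0)

    def test_mean_cc_near_edge_probability(self):
        # ER expectation: local clustering -> p
        n, p = 20, 0.3
        m = round(p * n * (n - 1) / 2)
        dists = er_baseline(n, m, reps=400, seed=1, louvain_restarts=1)
        cc = dists["cc"].values
        se = cc.std(ddof=1) / np.sqrt(len(cc))
        assert abs(cc.mean() - p) < 3 * se + 0.01

    def test_seeded_bit_reproducibility(self):
        a = er_baseline(12, 20, reps=30, seed=42, louvain_restarts=2)
        b = er_baseline(12, 20, reps=30, seed=42, louvain_restarts=2)
        for name in ("aspl", "cc", "q"):
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_invalid_density_rejected(self):
        with pytest.raises(ConfigurationError):
            er_baseline(5, 11, reps=2, seed=0)  # p > 1


class TestZTest:
    def test_observed_at_mean(self):
        dist = MetricDistribution("m", np.array([1.0, 2.0, 3.0]), "random-baseline")
        res = z_test(2.0, dist)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_one_sd_above(self):
        dist = MetricDistribution("m", np.array([1.0, 2.0, 3.0]), "random-baseline")
        res = z_test(3.0, dist)
        assert res.statistic == pytest.approx(1.0)

    def test_closed_form(self):
        import scipy.stats as st

        rng = np.random.default_rng(0)
        vals = rng.normal(5, 2, 100)
        dist = MetricDistribution("m", vals, "random-baseline")
        res = z_test(7.5, dist)
        z = (7.5 - vals.mean()) / vals.std(ddof=1)
        assert res.statistic == pytest.approx(z)
        assert res.p == pytest.approx(2 * st.norm.sf(abs(z)))

    def test_zero_spread_raises(self):
        dist = MetricDistribution("m", np.array([1.0, 1.0]), "random-baseline")
        with pytest.raises(DegenerateDistributionError):
            z_test(1.0, dist)


class TestCompareDistributions:
    def test_identical_distributions(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        a = MetricDistribution("m", vals, "bootstrap")
        b = MetricDistribution("m", vals, "bootstrap")
        res = compare_distributions(a, b)
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_textbook_formula(self):
        import scipy.stats as st

        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1.2, 60)
        res = compare_distributions(
            MetricDistribution("m", x, "bootstrap"),
            MetricDistribution("m", y, "bootstrap"),
        )
        t, p = st.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.df == 98
        sp = np.sqrt(((39 * x.var(ddof=1)) + 59 * y.var(ddof=1)) / 98)
        assert res.effect_size == pytest.approx((x.mean() - y.mean()) / sp)

    def test_unit_pooled_sd_gives_d_of_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 5000)
        y = x + 1.0
        res = compare_distributions(
            MetricDistribution("m", y, "bootstrap"),
            MetricDistribution("m", x, "bootstrap"),
        )
        assert res.effect_size == pytest.approx(1.0, abs=0.01)


class TestPairedComparisons:
    def test_equal_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t(x, x)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_shift_recovers_delta(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        y = x - 0.7 + rng.normal(0, 0.1, 50)
        res = paired_t(x, y)
        diff = x - y
        assert res.effect_size == pytest.approx(diff.mean() / diff.std(ddof=1))
        assert res.df == 49

    def test_closed_form(self):
        import scipy.stats as st

        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
        res = paired_t(x, y)
        t, p = st.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_mismatched_words_rejected(self):
        rng = np.random.default_rng(4)
        net1 = tmfg_filter(random_similarity(6, rng))
        loc1 = local_metrics(net1)
        net2 = tmfg_filter(random_similarity(7, rng))
        loc2 = local_metrics(net2)
        with pytest.raises(ConfigurationError):
            compare_local_metrics(loc1, loc2)


class TestBootstrap:
    def test_proportion_one_reproduces_full_network(self):
        rng = np.random.default_rng(12)
        a = random_binary_matrix(20, 12, rng)
        b = random_binary_matrix(18, 12, rng)
        boot = bootstrap_partial_networks(a, b, reps=5, proportion=1.0, seed=0,
                                          louvain_restarts=3)
        full_a = tmfg_filter(cosine_similarity(a))
        assert np.allclose(boot.distributions["aspl"][0].values, aspl(full_a))
        assert np.allclose(boot.distributions["cc"][0].values, global_cc(full_a))
        for name in ("aspl", "cc"):
            for which in (0, 1):
                assert boot.distributions[name][which].values.std() == 0.0

    def test_requires_equated_matrices(self):
        rng = np.random.default_rng(13)
        a = random_binary_matrix(10, 8, rng)
        b = random_binary_matrix(10, 9, rng)
        with pytest.raises(ConfigurationError):
            bootstrap_partial_networks(a, b, reps=2)

    def test_subset_too_small_rejected(self):
        rng = np.random.default_rng(14)
        a = random_binary_matrix(10, 6, rng)
        b = random_binary_matrix(10, 6, rng)
        with pytest.raises(ConfigurationError):
            bootstrap_partial_networks(a, b, reps=2, proportion=0.3)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(15)
        a = random_binary_matrix(15, 10, rng)
        b = random_binary_matrix(15, 10, rng)
        r1 = bootstrap_partial_networks(a, b, reps=8, seed=9, louvain_restarts=2)
        r2 = bootstrap_partial_networks(a, b, reps=8, seed=9, louvain_restarts=2)
        for name in ("aspl", "cc", "q"):
            np.testing.assert_array_equal(
                r1.distributions[name][0].values, r2.distributions[name][0].values
            )
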