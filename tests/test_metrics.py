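"""Graph metrics against analytic values and brute-force enumeration."""

import numpy as np
import networkx as nx
import pytest

from stresscov.metrics import (
    degree_ranks,
    global_metrics,
    mean_clustering,
    modularity_louvain,
    nodal_metrics,
    partition_modularity,
    path_length,
    transitivity,
    _betweenness_closeness,
)
from stresscov.networks import CovarianceNetwork

from .conftest import random_network
from .oracles import (
    brute_betweenness,
    brute_closeness,
    brute_clustering,
    brute_path_length,
    brute_transitivity,
)


def _net(w, density=0.5):
    n = w.shape[0]
    return CovarianceNetwork(
        group="control",
        roi_labels=[f"n{i}" for i in range(n)],
        weights=w,
        density=density,
        retained_edges=int(np.count_nonzero(np.triu(w, 1))),
    )


def triangle(weight=1.0):
    w = np.zeros((3, 3))
    for a, b in [(0, 1), (1, 2), (0, 2)]:
        w[a, b] = w[b, a] = weight
    return w


class TestAnalyticFixtures:
    def test_uniform_triangle_is_fully_clustered(self):
        w = triangle(0.5)
        assert transitivity(w) == pytest.approx(1.0)
        assert mean_clustering(w) == pytest.approx(1.0)
        pl, ncomp = path_length(w)
        assert pl == pytest.approx(1.0 / 0.5)
        assert ncomp == 1

    def test_path_graph_has_no_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert transitivity(w) == 0.0
        assert mean_clustering(w) == 0.0

    def test_two_disjoint_triangles_modularity_half(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            w[a, b] = w[b, a] = 1.0
        part = np.array([0, 0, 0, 1, 1, 1])
        assert partition_modularity(w, part) == pytest.approx(0.5)
        q, found = modularity_louvain(w, runs=5, seed=0)
        assert q == pytest.approx(0.5)
        assert len(np.unique(found)) == 2

    def test_star_center_betweenness_one_leaves_zero(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 1.0
        nm = nodal_metrics(_net(w))
        assert nm.degree[0] == 4
        assert nm.betweenness[0] == pytest.approx(1.0)
        assert nm.degree[1] == 1
        assert nm.betweenness[1] == pytest.approx(0.0)
        assert nm.degree_rank[0] == 1

    def test_complete_uniform_graph_modularity_zero(self):
        w = np.ones((8, 8))
        np.fill_diagonal(w, 0.0)
        q, _ = modularity_louvain(w, runs=3, seed=1)
        assert q == pytest.approx(0.0, abs=1e-12)


class TestBruteForceOracles:
    """Fast implementations must match exhaustive enumeration on small graphs."""

    @pytest.mark.parametrize("trial", range(25))
    def test_metrics_match_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 8))
        net = random_network(rng, n, p_edge=float(rng.uniform(0.35, 0.9)))
        w = net.weights
        if not np.any(w > 0):
            pytest.skip("empty draw")
        assert transitivity(w) == pytest.approx(brute_transitivity(w), abs=1e-9)
        assert mean_clustering(w) == pytest.approx(brute_clustering(w), abs=1e-9)
        assert path_length(w)[0] == pytest.approx(brute_path_length(w), abs=1e-9)
        bc, cc = _betweenness_closeness(w)
        np.testing.assert_allclose(bc, brute_betweenness(w), atol=1e-9)
        np.testing.assert_allclose(cc, brute_closeness(w), atol=1e-9)

    def test_betweenness_closeness_match_networkx(self, rng):
        """Independent cross-check against a second implementation."""
        for _ in range(10):
            net = random_network(rng, 9, p_edge=0.5)
            w = net.weights
            g = nx.from_numpy_array(w)
            for u, v, dat in g.edges(data=True):
                dat["dist"] = 1.0 / dat["weight"]
            bc, cc = _betweenness_closeness(w)
            nx_bc = nx.betweenness_centrality(g, weight="dist", normalized=True)
            nx_cc = nx.closeness_centrality(g, distance="dist", wf_improved=True)
            np.testing.assert_allclose(bc, [nx_bc[i] for i in range(9)], atol=1e-9)
            np.testing.assert_allclose(cc, [nx_cc[i] for i in range(9)], atol=1e-9)

    def test_louvain_matches_networkx_quality(self, rng):
        """Louvain's best Q should not fall below networkx's on the same graph."""
        for s in range(5):
            net = random_network(rng, 20, p_edge=0.3)
            w = net.weights
            if not np.any(w > 0):
                continue
            q, _ = modularity_louvain(w, runs=20, seed=s)
            g = nx.from_numpy_array(w)
            comms = nx.community.louvain_communities(g, weight="weight", seed=s)
            part = np.zeros(20, dtype=int)
            for ci, nodes in enumerate(comms):
                for nd in nodes:
                    part[nd] = ci
            q_nx = partition_modularity(w, part)
            assert q >= q_nx - 1e-9


class TestInvariants:
    def test_weight_scale_invariance(self, rng):
        net = random_network(rng, 10, p_edge=0.5)
        w = net.weights
        c = 3.7
        assert transitivity(c * w) == pytest.approx(transitivity(w))
        assert mean_clustering(c * w) == pytest.approx(mean_clustering(w))
        assert path_length(c * w)[0] == pytest.approx(path_length(w)[0] / c)
        nm1, nm2 = nodal_metrics(_net(w)), nodal_metrics(_net(c * w))
        np.testing.assert_allclose(nm2.strength, c * nm1.strength)
        np.testing.assert_array_equal(
            np.argsort(nm1.betweenness), np.argsort(nm2.betweenness)
        )
        q1, _ = modularity_louvain(w, runs=5, seed=3)
        q2, _ = modularity_louvain(c * w, runs=5, seed=3)
        assert q1 == pytest.approx(q2)

    def test_more_restarts_never_decrease_q(self, rng):
        net = random_network(rng, 15, p_edge=0.4)
        w = net.weights
        qs = [modularity_louvain(w, runs=r, seed=11)[0] for r in (1, 3, 10)]
        assert qs[0] <= qs[1] <= qs[2]

    def test_degree_ranks_min_rank_ties(self):
        ranks = degree_ranks(np.array([5, 3, 5, 1]))
        np.testing.assert_array_equal(ranks, [1, 3, 1, 4])

    def test_disconnected_components_counted_and_pairs_excluded(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 0.5
        pl, ncomp = path_length(w)
        assert ncomp == 3  # two dyads plus an isolated node
        assert pl == pytest.approx((1.0 + 2.0) / 2)

    def test_empty_graph_rejected(self):
        w = np.zeros((4, 4))
        with pytest.raises(ValueError, match="empty"):
            global_metrics(_net(w, density=0.01))

    def test_global_metrics_bundle(self, rng):
        net = random_network(rng, 12, p_edge=0.6)
        gm = global_metrics(net, modularity_runs=10, seed=5)
        assert 0 <= gm.transitivity <= 1
        assert 0 <= gm.clustering_coefficient <= 1
        assert -0.5 <= gm.modularity <= 1
        assert gm.path_length > 0
        assert gm.n_components >= 1
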