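"""Graph measures: closed forms, oracle equivalence, scaling and invariances."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import as_rectified, random_weighted_graph
from fcnet.metrics import (
    MetricCurve,
    betweenness_centrality,
    clustering_coefficient,
    distance_matrix,
    global_efficiency,
    local_efficiency,
    metric_auc,
    node_strength,
    nodal_metrics,
    shortest_paths,
    to_length_matrix,
)
from fcnet.network import threshold_to_sparsity


def complete(n):
    return np.ones((n, n)) - np.eye(n)


def ring(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return w


def star(n_leaves):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


def path(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


class TestClosedForms:
    def test_strength_examples(self):
        np.testing.assert_array_equal(node_strength(complete(3)), [2, 2, 2])
        np.testing.assert_array_equal(node_strength(0.5 * complete(3)), [1, 1, 1])
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1
        assert node_strength(w)[2] == 0

    def test_length_mapping(self):
        w = np.array([[0, 0.5, 0], [0.5, 0, 1.0], [0, 1.0, 0]])
        lengths = to_length_matrix(w)
        assert lengths[0, 1] == 2.0
        assert lengths[1, 2] == 1.0
        assert np.isinf(lengths[0, 2])
        assert lengths[0, 0] == 0.0

    def test_path_distance_and_indirect_shortcut(self):
        d, counts = shortest_paths(to_length_matrix(path(3)))
        assert d[0, 2] == 2.0
        # triangle where the direct a-c edge (w=0.4 -> L=2.5) loses to a-b-c
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 0.4
        d, _ = shortest_paths(to_length_matrix(w))
        assert d[0, 2] == pytest.approx(2.0)

    def test_betweenness_star_and_path(self):
        bc = betweenness_centrality(star(3))
        np.testing.assert_allclose(bc, [1.0, 0, 0, 0])
        bc = betweenness_centrality(path(3))
        assert bc[1] == pytest.approx(1.0)

    def test_clustering_examples(self):
        np.testing.assert_allclose(clustering_coefficient(complete(3)), [1, 1, 1])
        np.testing.assert_array_equal(clustering_coefficient(path(4)), np.zeros(4))
        w = complete(3)
        w[1, 2] = w[2, 1] = 0.5
        assert clustering_coefficient(w)[0] == pytest.approx(0.5 ** (1 / 3))

    def test_efficiency_closed_forms(self):
        assert global_efficiency(complete(5)) == pytest.approx(1.0)
        assert global_efficiency(ring(4)) == pytest.approx(5 / 6)
        np.testing.assert_allclose(local_efficiency(complete(4)), np.ones(4))
        np.testing.assert_allclose(local_efficiency(star(4)), np.zeros(5))
        np.testing.assert_allclose(local_efficiency(complete(3)), np.ones(3))

    def test_binary_reduction_matches_hop_counts(self):
        """Unit weights reduce every measure to its binary textbook value."""
        for g in (complete(5), star(4), ring(6), path(5)):
            lengths = to_length_matrix(g)
            d, _ = shortest_paths(lengths)
            G = nx.from_numpy_array(g)
            hop = dict(nx.all_pairs_shortest_path_length(G))
            for i in range(g.shape[0]):
                for j in range(g.shape[0]):
                    assert d[i, j] == hop[i][j]


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(42)
    out = []
    for _ in range(100):
        n = int(rng.integers(4, 9))
        out.append(random_weighted_graph(rng, n, density=0.7))
    return out


class TestOracleEquivalence:
    def test_distances_and_counts_match_networkx(self, graphs):
        for w in graphs:
            n = w.shape[0]
            G = nx.from_numpy_array(w)
            for u, v, d in G.edges(data=True):
                d["length"] = 1.0 / d["weight"]
            d_me, counts = shortest_paths(to_length_matrix(w))
            d_fw = distance_matrix(to_length_matrix(w))
            nx_d = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
            for i in range(n):
                for j in range(n):
                    ref = nx_d[i].get(j, np.inf)
                    if np.isinf(ref):
                        assert np.isinf(d_me[i, j]) and counts[i, j] == 0
                    else:
                        assert d_me[i, j] == pytest.approx(ref, abs=1e-9)
                        assert d_fw[i, j] == pytest.approx(ref, abs=1e-9)

    def test_betweenness_matches_networkx(self, graphs):
        for w in graphs:
            n = w.shape[0]
            G = nx.from_numpy_array(w)
            for u, v, d in G.edges(data=True):
                d["length"] = 1.0 / d["weight"]
            ref = nx.betweenness_centrality(G, weight="length", normalized=True)
            mine = betweenness_centrality(w)
            np.testing.assert_allclose(mine, [ref[i] for i in range(n)], atol=1e-9)

    def test_betweenness_matches_brute_force_path_enumeration(self):
        """Independent oracle: enumerate ALL simple paths, find the shortest,
        and count fractional pass-throughs (no Dijkstra, no Brandes)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 6
            w = random_weighted_graph(rng, n, density=0.8)
            lengths = to_length_matrix(w)
            raw = np.zeros(n)
            for s, t in itertools.permutations(range(n), 2):
                best, paths = np.inf, []
                for k in range(n):
                    for mid in itertools.permutations(
                        [x for x in range(n) if x not in (s, t)], k
                    ):
                        nodes = (s, *mid, t)
                        L = sum(lengths[a, b] for a, b in zip(nodes, nodes[1:]))
                        if not np.isfinite(L):
                            continue
                        if L < best - 1e-12:
                            best, paths = L, [nodes]
                        elif abs(L - best) <= 1e-12:
                            paths.append(nodes)
                if not np.isfinite(best):
                    continue
                for p in paths:
                    for v in p[1:-1]:
                        raw[v] += 1.0 / len(paths)
            np.testing.assert_allclose(
                betweenness_centrality(w, normalized=False), raw, atol=1e-9
            )

    def test_efficiencies_match_brute_force(self, graphs):
        for w in graphs[:50]:
            n = w.shape[0]
            G = nx.from_numpy_array(w)
            for u, v, d in G.edges(data=True):
                d["length"] = 1.0 / d["weight"]
            nx_d = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
            acc = [
                1.0 / nx_d[i][j]
                for i in range(n) for j in range(n)
                if i != j and j in nx_d[i]
            ]
            eg_ref = sum(acc) / (n * (n - 1))
            assert global_efficiency(w) == pytest.approx(eg_ref, abs=1e-9)
            # subgraph local efficiency against the same oracle per node
            eloc = local_efficiency(w)
            for i in range(n):
                nbrs = np.flatnonzero(w[i] > 0)
                if nbrs.size < 2:
                    assert eloc[i] == 0
                    continue
                sub = w[np.ix_(nbrs, nbrs)]
                Gs = nx.from_numpy_array(sub)
                for u, v, d in Gs.edges(data=True):
                    d["length"] = 1.0 / d["weight"]
                ds = dict(nx.all_pairs_dijkstra_path_length(Gs, weight="length"))
                m = nbrs.size
                acc = [
                    1.0 / ds[a][b]
                    for a in range(m) for b in range(m)
                    if a != b and b in ds[a]
                ]
                assert eloc[i] == pytest.approx(sum(acc) / (m * (m - 1)), abs=1e-9)


class TestScalingAndInvariance:
    def test_weight_scaling(self):
        rng = np.random.default_rng(3)
        w = random_weighted_graph(rng, 7)
        c = 3.7
        np.testing.assert_allclose(
            betweenness_centrality(c * w), betweenness_centrality(w), atol=1e-9
        )
        np.testing.assert_allclose(
            clustering_coefficient(c * w), clustering_coefficient(w), atol=1e-12
        )
        np.testing.assert_allclose(node_strength(c * w), c * node_strength(w))
        assert global_efficiency(c * w) == pytest.approx(c * global_efficiency(w))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        w = random_weighted_graph(rng, 8)
        perm = rng.permutation(8)
        wp = w[np.ix_(perm, perm)]
        nm, nmp = nodal_metrics(w), nodal_metrics(wp)
        for name in ("bc", "strength", "cc", "eloc"):
            np.testing.assert_allclose(
                getattr(nmp, name), getattr(nm, name)[perm], atol=1e-9
            )
        assert nmp.eglob == pytest.approx(nm.eglob, abs=1e-12)

    def test_eglob_nondecreasing_in_sparsity(self):
        rng = np.random.default_rng(6)
        w = random_weighted_graph(rng, 20, density=0.9)
        values = [
            global_efficiency(threshold_to_sparsity(as_rectified(w), s).weights)
            for s in np.arange(0.08, 0.2601, 0.02)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_toolbox_eloc_variant_agrees_on_uniform_weights(self):
        # on a unit-weight clique both local-efficiency forms are exactly 1
        w = complete(5)
        np.testing.assert_allclose(local_efficiency(w, "toolbox"), np.ones(5))
        rng = np.random.default_rng(8)
        wr = random_weighted_graph(rng, 7)
        out = local_efficiency(wr, "toolbox")
        assert np.isfinite(out).all() and (out >= 0).all()


class TestMetricAuc:
    def test_constant_and_ramp(self):
        grid = np.arange(0.08, 0.2601, 0.01)
        const = MetricCurve(grid, np.full(grid.size, 3.0))
        assert metric_auc(const) == pytest.approx(0.18 * 3.0)
        ramp = MetricCurve(grid, np.linspace(0, 1, grid.size))
        assert metric_auc(ramp) == pytest.approx(0.09)

    def test_collinear_midpoint_invariance(self):
        c1 = MetricCurve([0.1, 0.3], [1.0, 2.0])
        c2 = MetricCurve([0.1, 0.2, 0.3], [1.0, 1.5, 2.0])
        assert metric_auc(c1) == pytest.approx(metric_auc(c2))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            metric_auc(MetricCurve([0.1], [1.0]))
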