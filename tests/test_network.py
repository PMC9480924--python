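"""Network construction: correlation, residualisation, thresholding, sparsity."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import as_rectified
from fcnet.network import (
    UNREACHABLE,
    ConnectivityMatrix,
    ROITimeSeries,
    largest_component_size,
    min_connecting_sparsity,
    network_sparsity,
    pearson_connectivity,
    rectify_negative,
    residualize_edges,
    select_group_sparsity,
    threshold_to_sparsity,
)


def ts(data, sid="s1"):
    data = np.asarray(data, dtype=float)
    return ROITimeSeries(sid, data, [f"n{i}" for i in range(data.shape[1])])


class TestPearsonConnectivity:
    def test_identical_and_anticorrelated_columns(self):
        x = np.arange(6.0)
        w = pearson_connectivity(ts(np.column_stack([x, x, -x]))).weights
        assert w[0, 1] == pytest.approx(1.0)
        assert w[0, 2] == pytest.approx(-1.0)
        assert np.diag(w).max() == 0.0

    def test_hand_computed_r(self):
        w = pearson_connectivity(ts(np.array([[1, 1], [2, 3], [3, 2], [4, 4]]))).weights
        assert w[0, 1] == pytest.approx(0.8)

    def test_constant_column_names_the_node(self):
        bad = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="n1"):
            pearson_connectivity(ts(bad))


def _matrices_from_edges(edge_vectors, n):
    iu = np.triu_indices(n, 1)
    out = []
    for k, v in enumerate(edge_vectors):
        w = np.zeros((n, n))
        w[iu] = v
        out.append(ConnectivityMatrix(w + w.T, stage="raw", subject_id=f"s{k}"))
    return out


class TestResidualizeEdges:
    def _subjects(self, ages, sexes):
        return pd.DataFrame({"age": ages, "sex": sexes})

    def test_orthogonal_edges_unchanged(self):
        rng = np.random.default_rng(0)
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        sexes = ["F", "M", "F", "M"]
        base = rng.uniform(0.1, 0.5, 6)
        # identical edges across subjects: orthogonal to any covariate
        mats = _matrices_from_edges([base] * 4, 4)
        out = residualize_edges(mats, self._subjects(ages, sexes))
        for m_in, m_out in zip(mats, out):
            np.testing.assert_allclose(m_out.weights, m_in.weights, atol=1e-10)

    def test_pure_age_effect_collapses_to_grand_mean(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        sexes = ["F", "M", "M", "F"]  # balanced, orthogonal-ish to age
        edge_vectors = [np.full(6, 0.01 * a) for a in ages]
        out = residualize_edges(_matrices_from_edges(edge_vectors, 4),
                                self._subjects(ages, sexes))
        grand = 0.01 * ages.mean()
        iu = np.triu_indices(4, 1)
        for m in out:
            np.testing.assert_allclose(m.weights[iu], grand, atol=1e-10)

    def test_subject_order_equivariance(self):
        rng = np.random.default_rng(1)
        mats = _matrices_from_edges(rng.uniform(-0.3, 0.8, (5, 10)), 5)
        subj = self._subjects(rng.uniform(20, 60, 5), ["F", "M", "F", "M", "F"])
        out = residualize_edges(mats, subj)
        perm = [3, 1, 4, 0, 2]
        out_p = residualize_edges([mats[i] for i in perm], subj.iloc[perm])
        for k, i in enumerate(perm):
            np.testing.assert_allclose(out_p[k].weights, out[i].weights, atol=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        mats = _matrices_from_edges(rng.uniform(-0.3, 0.8, (6, 15)), 6)
        subj = self._subjects(rng.uniform(20, 60, 6), ["F", "M"] * 3)
        once = residualize_edges(mats, subj)
        twice = residualize_edges(once, subj)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-10)

    def test_single_sex_cohort_drops_covariate_with_warning(self):
        rng = np.random.default_rng(3)
        mats = _matrices_from_edges(rng.uniform(0, 0.5, (4, 6)), 4)
        subj = self._subjects([20.0, 30, 40, 50], ["F"] * 4)
        with pytest.warns(UserWarning, match="sex"):
            residualize_edges(mats, subj)


class TestRectifyAndSparsity:
    def test_rectify_cases(self):
        w = np.array([[0, 0.5, -0.2], [0.5, 0, -0.7], [-0.2, -0.7, 0]])
        m = rectify_negative(ConnectivityMatrix(w, stage="residualized"))
        assert (m.weights >= 0).all()
        assert m.weights[0, 1] == 0.5 and m.weights[1, 2] == 0.0
        # idempotent
        np.testing.assert_array_equal(rectify_negative(m).weights, m.weights)

    def test_sparsity_examples(self):
        k4 = np.ones((4, 4)) - np.eye(4)
        assert network_sparsity(k4) == 1.0
        assert network_sparsity(np.zeros((5, 5))) == 0.0
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            w[i, j] = w[j, i] = 0.5
        assert network_sparsity(w) == 0.5


class TestThresholdToSparsity:
    def test_distinct_weights_keep_largest(self):
        rng = np.random.default_rng(0)
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        vals = np.array([0.9, 0.1, 0.5, 0.3, 0.8, 0.2])
        w[iu] = vals
        w = w + w.T
        tn = threshold_to_sparsity(as_rectified(w), 0.5)
        kept = tn.weights[iu]
        assert sorted(kept[kept > 0]) == sorted([0.9, 0.8, 0.5])
        assert tn.sparsity == 0.5

    def test_tie_break_is_lexicographic_and_stable(self):
        w = np.full((4, 4), 0.4) - 0.4 * np.eye(4)
        first = threshold_to_sparsity(as_rectified(w), 0.5)
        again = threshold_to_sparsity(as_rectified(w), 0.5)
        iu = np.triu_indices(4, 1)
        assert np.count_nonzero(first.weights[iu]) == 3
        # lexicographically first edges (0,1), (0,2), (0,3) survive
        assert first.weights[0, 1] > 0 and first.weights[0, 2] > 0 and first.weights[0, 3] > 0
        np.testing.assert_array_equal(first.weights, again.weights)

    def test_shortfall_warns_and_keeps_all_positive(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.warns(UserWarning, match="positive edges"):
            tn = threshold_to_sparsity(as_rectified(w), 0.9)
        assert np.count_nonzero(tn.weights) == 2
        assert tn.sparsity < 0.9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 1.0))
    def test_achieved_sparsity_within_one_edge(self, seed, target):
        rng = np.random.default_rng(seed)
        n = 10
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0.01, 1, iu[0].size)
        w = w + w.T
        tn = threshold_to_sparsity(as_rectified(w), target)
        m = n * (n - 1) / 2
        assert abs(tn.sparsity - target) <= 1 / m + 1e-12

    def test_nestedness_and_lcc_monotone_over_grid(self):
        rng = np.random.default_rng(5)
        n = 20
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0, 1, iu[0].size) * (rng.random(iu[0].size) < 0.6)
        w = w + w.T
        prev_edges = None
        prev_lcc = 0
        for s in np.arange(0.08, 0.2601, 0.01):
            tn = threshold_to_sparsity(as_rectified(w), s)
            edges = set(zip(*np.nonzero(np.triu(tn.weights, 1))))
            if prev_edges is not None:
                assert prev_edges <= edges
            assert tn.lcc_size >= prev_lcc
            prev_edges, prev_lcc = edges, tn.lcc_size


class TestComponentsAndConnectingSparsity:
    def test_largest_component_examples(self):
        ring = np.zeros((5, 5))
        for i in range(5):
            ring[i, (i + 1) % 5] = ring[(i + 1) % 5, i] = 1
        assert largest_component_size(ring) == 5
        two_tri = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            two_tri[a, b] = two_tri[b, a] = 1
        assert largest_component_size(two_tri) == 3
        assert largest_component_size(np.zeros((7, 7))) == 1

    def test_spanning_tree_ordered_weights(self):
        """When the N-1 strongest edges form a tree the minimum is 2/N."""
        n = 8
        w = np.zeros((n, n))
        for i in range(n - 1):  # path edges strongest
            w[i, i + 1] = w[i + 1, i] = 0.9 - 0.01 * i
        w[0, 2] = w[2, 0] = 0.1  # weaker extra edge
        s = min_connecting_sparsity(as_rectified(w))
        assert s == pytest.approx(2 / n)

    def test_triangle_plus_pendant_needs_four_edges(self):
        w = np.zeros((4, 4))
        for (i, j), v in zip([(0, 1), (0, 2), (1, 2)], [0.9, 0.8, 0.7]):
            w[i, j] = w[j, i] = v
        w[2, 3] = w[3, 2] = 0.1
        assert min_connecting_sparsity(as_rectified(w)) == pytest.approx(4 / 6)

    def test_strengthening_kept_edge_never_raises_minimum(self):
        rng = np.random.default_rng(7)
        n = 10
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        w[iu] = rng.uniform(0.05, 1, iu[0].size)
        w = w + w.T
        s0 = min_connecting_sparsity(as_rectified(w))
        strongest = np.unravel_index(np.argmax(np.triu(w, 1)), w.shape)
        w2 = w.copy()
        w2[strongest] = w2[strongest[::-1]] = 2.0
        assert min_connecting_sparsity(as_rectified(w2)) <= s0

    def test_isolated_node_is_unreachable(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 0.5
        with pytest.warns(UserWarning, match="degree"):
            assert min_connecting_sparsity(as_rectified(w)) == UNREACHABLE


class TestSelectGroupSparsity:
    def _subject_with_minimum(self, n, k_needed, sid):
        """Matrix whose connecting minimum is exactly k_needed edges: a clique
        on the first n-1 nodes, with the last node attached by an edge whose
        weight ranks exactly k_needed among all edges."""
        w = np.zeros((n, n))
        iu = list(zip(*np.triu_indices(n - 1, 1)))
        for idx, (i, j) in enumerate(iu):
            w[i, j] = w[j, i] = 0.9 - 1e-3 * idx
        vals = sorted(w[np.triu_indices(n, 1)], reverse=True)
        w[n - 2, n - 1] = w[n - 1, n - 2] = vals[k_needed - 2] - 1e-6
        return as_rectified(w, sid)

    def test_single_subject(self):
        m = self._subject_with_minimum(6, 7, "a")
        sel, lo = select_group_sparsity([m])
        assert sel == lo == round(7 / 15 * 1000) / 1000

    def test_max_and_min_over_subjects(self):
        mats = [
            self._subject_with_minimum(6, 6, "a"),
            self._subject_with_minimum(6, 9, "b"),
            self._subject_with_minimum(6, 11, "c"),
        ]
        sel, lo = select_group_sparsity(mats)
        assert sel == round(11 / 15 * 1000) / 1000
        assert lo == round(6 / 15 * 1000) / 1000

    def test_duplicate_subject_invariance(self):
        mats = [self._subject_with_minimum(6, 6, "a"),
                self._subject_with_minimum(6, 9, "b")]
        assert select_group_sparsity(mats) == select_group_sparsity(mats + [mats[0]])

    def test_unreachable_subject_raises_with_id(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="lonely"):
                select_group_sparsity([as_rectified(w, "lonely")])

    def test_reported_magnitudes_follow_definition(self):
        """Per-subject minima {8.1%, 15%, 26.2%} map to (26.2%, 8.1%)."""
        n = 112
        m = n * (n - 1) // 2
        minima = {"a": 0.081, "b": 0.15, "c": 0.262}
        mats = [
            self._subject_with_minimum_large(n, int(round(v * m)), sid)
            for sid, v in minima.items()
        ]
        sel, lo = select_group_sparsity(mats)
        assert sel == pytest.approx(0.262, abs=5e-4)
        assert lo == pytest.approx(0.081, abs=5e-4)

    def _subject_with_minimum_large(self, n, k_needed, sid):
        rng = np.random.default_rng(hash(sid) % 2**31)
        w = np.zeros((n, n))
        iu = list(zip(*np.triu_indices(n - 1, 1)))
        vals = np.sort(rng.uniform(0.5, 0.9, len(iu)))[::-1]
        for (i, j), v in zip(iu, vals):
            w[i, j] = w[j, i] = v
        ordered = np.sort(w[np.triu_indices(n, 1)])[::-1]
        w[n - 2, n - 1] = w[n - 1, n - 2] = ordered[k_needed - 2] - 1e-9
        return as_rectified(w, sid)


class TestPipelineEquivariance:
    def test_node_relabeling_permutes_outputs(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((50, 8))
        w = pearson_connectivity(ts(data)).weights
        perm = rng.permutation(8)
        w_p = pearson_connectivity(ts(data[:, perm])).weights
        np.testing.assert_allclose(w_p, w[np.ix_(perm, perm)], atol=1e-12)
        tn = threshold_to_sparsity(as_rectified(np.maximum(w, 0)), 0.4)
        tn_p = threshold_to_sparsity(as_rectified(np.maximum(w_p, 0)), 0.4)
        # same sparsity and (generic weights) the permuted edge set
        np.testing.assert_allclose(
            tn_p.weights, tn.weights[np.ix_(perm, perm)], atol=1e-12
        )
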