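"""Multi-view pooling: view scores, PageRank propagation, fusion, top-rank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphadt import (MVPool, ViewScores, attention_fuse, feature_score,
                      pagerank_score, structure_score, top_rank, top_rank_pool)
from graphadt.autodiff import Tensor
from graphadt.errors import NonConvergenceWarning
from graphadt.pooling import _normalized_adjacency, _sigmoid


def _random_graph(rng, n, p=0.4):
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


class TestStructureScore:
    def test_isolated_node(self):
        A = np.zeros((1, 1))
        s = structure_score(A, alpha=1.0, beta=0.0, eps=1e-5)
        assert abs(s[0] - _sigmoid(np.log(1e-5))) < 1e-12
        assert abs(s[0] - 1.0000500e-5) < 1e-8

    def test_degree_one(self):
        A = np.array([[0, 1], [1, 0]], dtype=float)
        s = structure_score(A, alpha=1.0, beta=0.0)
        assert np.allclose(s, _sigmoid(np.log(1 + 1e-5)))
        assert abs(s[0] - 0.5000025) < 1e-6

    def test_alpha_zero_is_constant(self, rng):
        A = _random_graph(rng, 8)
        s = structure_score(A, alpha=0.0, beta=0.7)
        assert np.allclose(s, _sigmoid(0.7))

    def test_requires_positive_eps(self):
        with pytest.raises(ValueError):
            structure_score(np.zeros((2, 2)), 1.0, 0.0, eps=0.0)


class TestFeatureScore:
    def test_zero_input_zero_bias_gives_half(self):
        Z = np.zeros((5, 3))
        s = feature_score(Z, (np.zeros(3), 0.0))
        assert np.allclose(s, 0.5)

    def test_identical_rows_identical_scores(self, rng):
        row = rng.normal(size=4)
        Z = np.stack([row, row, rng.normal(size=4)])
        s = feature_score(Z, (rng.normal(size=4), 0.3))
        assert s[0] == s[1]

    def test_single_layer_definition(self, rng):
        Z = rng.normal(size=(6, 3))
        w, b = rng.normal(size=3), 0.2
        assert np.allclose(feature_score(Z, (w, b)), _sigmoid(Z @ w + b))


class TestPagerankScore:
    def test_delta_one_no_propagation(self, rng):
        A = _random_graph(rng, 6)
        Z = rng.normal(size=(6, 4))
        phi = rng.normal(size=4)
        seed = _sigmoid(_normalized_adjacency(A, 1) @ (Z @ phi))
        assert np.allclose(pagerank_score(A, Z, phi, delta=1.0), _sigmoid(seed))

    def test_two_node_closed_form(self, rng):
        A = np.array([[0, 1], [1, 0]], dtype=float)
        Z = rng.normal(size=(2, 3))
        phi = rng.normal(size=3)
        p_power = pagerank_score(A, Z, phi, delta=0.2, n_iter=500, tol=1e-12)
        p_dense = pagerank_score(A, Z, phi, delta=0.2, method="dense")
        assert np.max(np.abs(p_power - p_dense)) < 1e-6

    def test_symmetric_seed_gives_symmetric_scores(self):
        A = np.array([[0, 1], [1, 0]], dtype=float)
        Z = np.ones((2, 2))
        phi = np.ones(2)
        p = pagerank_score(A, Z, phi, delta=0.3)
        assert abs(p[0] - p[1]) < 1e-12

    def test_nonconvergence_warns_but_returns(self, rng):
        A = (np.eye(5, k=1) + np.eye(5, k=-1))  # path graph: propagation mixes
        Z = rng.normal(size=(5, 2))
        with pytest.warns(NonConvergenceWarning):
            p = pagerank_score(A, Z, rng.normal(size=2), delta=0.05,
                               n_iter=1, tol=1e-15)
        assert p.shape == (5,)


class TestAttentionFuse:
    def test_identical_params_give_uniform_weights(self, rng):
        scores = ViewScores(rng.random(5), rng.random(5), rng.random(5))
        w = np.tile(rng.normal(size=3)[:, None], (1, 3))  # identical columns w_j
        b = np.full(3, 0.1)
        g, _ = attention_fuse(scores, w, b)
        assert np.allclose(g, 1 / 3)

    def test_identical_views_fuse_to_themselves(self, rng):
        v = rng.random(7)
        g, p = attention_fuse(ViewScores(v, v, v), rng.normal(size=(3, 3)),
                              rng.normal(size=3))
        assert np.allclose(p, v)
        assert abs(g.sum() - 1.0) < 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 10_000))
    def test_fused_score_is_convex_combination(self, n, seed):
        r = np.random.default_rng(seed)
        scores = ViewScores(r.random(n), r.random(n), r.random(n))
        g, p = attention_fuse(scores, r.normal(size=(3, 3)), r.normal(size=3))
        stacked = np.stack([scores.p_c, scores.p_f, scores.p_cf])
        assert abs(g.sum() - 1.0) < 1e-9
        assert np.all(p >= stacked.min(axis=0) - 1e-12)
        assert np.all(p <= stacked.max(axis=0) + 1e-12)


class TestTopRankPool:
    @pytest.mark.parametrize("n,r,expected", [(4, 0.5, 2), (5, 0.5, 3),
                                              (1, 0.1, 1), (7, 1.0, 7)])
    def test_cardinality_is_ceiling(self, n, r, expected, rng):
        assert len(top_rank(rng.random(n), r)) == expected

    def test_strict_max_single_retention(self, rng):
        p = np.array([0.1, 0.9, 0.2, 0.3])
        A = _random_graph(rng, 4)
        res = top_rank_pool(rng.normal(size=(4, 2)), A, p, r=0.25)
        assert list(res.ind) == [1]
        assert res.A_next.shape == (1, 1) and res.A_next[0, 0] == 0

    def test_gating_and_submatrix(self, rng):
        Z = rng.normal(size=(6, 3))
        A = _random_graph(rng, 6)
        p = rng.random(6)
        res = top_rank_pool(Z, A, p, r=0.5)
        assert np.allclose(res.Z_next, Z[res.ind] * _sigmoid(p[res.ind])[:, None])
        assert np.array_equal(res.A_next, A[np.ix_(res.ind, res.ind)])

    def test_tie_break_prefers_lower_index(self):
        p = np.array([0.5, 0.5, 0.5, 0.9])
        assert list(top_rank(p, 0.5)) == [0, 3]

    def test_permutation_equivariance_of_selection(self, rng):
        n = 10
        p = rng.random(n)  # continuous scores: ties have measure zero
        perm = rng.permutation(n)
        ind = top_rank(p, 0.4)
        ind_perm = top_rank(p[perm], 0.4)
        assert set(perm[ind_perm]) == set(ind)


class TestMVPoolLayer:
    def test_matches_functional_path_and_weights_sum(self, rng):
        n, d = 8, 6
        layer = MVPool(d, np.random.default_rng(1), pool_ratio=0.5)
        A = _random_graph(rng, n)
        Z = Tensor(rng.normal(size=(n, d)))
        p_c, p_f, p_cf = layer.view_scores(Z, A)
        for v in (p_c, p_f, p_cf):
            assert np.all((v.data > 0) & (v.data < 1))
        g, p = layer.fuse(p_c, p_f, p_cf)
        assert abs(g.data.sum() - 1.0) < 1e-9
        Z_next, A_next, _, ind = layer(Z, A)
        assert np.array_equal(ind, top_rank(p.data, 0.5))
        assert np.array_equal(A_next, A[np.ix_(ind, ind)])
        assert Z_next.shape == (len(ind), d)

    def test_dense_solve_agrees_with_functional_pagerank(self, rng):
        n, d = 7, 5
        layer = MVPool(d, np.random.default_rng(2), delta=0.2)
        A = _random_graph(rng, n)
        Z = rng.normal(size=(n, d))
        _, _, p_cf = layer.view_scores(Tensor(Z), A)
        expected = pagerank_score(A, Z, layer.phi.data, delta=0.2,
                                  method="dense")
        assert np.max(np.abs(p_cf.data - expected)) < 1e-10

    def test_invalid_hyperparameters_rejected(self):
        r = np.random.default_rng(0)
        with pytest.raises(ValueError):
            MVPool(4, r, pool_ratio=0.0)
        with pytest.raises(ValueError):
            MVPool(4, r, delta=1.5)
        with pytest.raises(ValueError):
            MVPool(4, r, k_power=0)
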