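"""One-class collaborative-filtering solver: objective, updates, ranking."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls

from remap3d import (
    SimilarityGraph,
    WeightScheme,
    fit,
    laplacian_quadratic,
    objective_value,
    predict_scores,
    rank_targets,
)

W1 = WeightScheme(1.0, 1.0, 1.0)  # uniform weights over every cell


class TestLaplacianQuadratic:
    def test_identical_rows_are_in_null_space(self):
        S = sp.csr_matrix(np.array([[0, 0.5, 0.2], [0.5, 0, 0.9], [0.2, 0.9, 0]]))
        U = np.tile([1.0, 2.0, 3.0], (3, 1))
        assert laplacian_quadratic(U, S) == pytest.approx(0.0, abs=1e-12)

    def test_empty_graph(self):
        assert laplacian_quadratic(np.ones((4, 2)), sp.csr_matrix((4, 4))) == 0.0

    def test_two_node_example(self):
        S = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        # 0.5 * sum S_ij ||U_i - U_j||^2 = 0.5 * 2 * 2 = 2
        assert laplacian_quadratic(U, S) == pytest.approx(2.0)

    def test_asymmetric_matrix_rejected(self):
        S = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_quadratic(np.ones((2, 2)), S)

    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=1000))
    @settings(max_examples=40, deadline=None)
    def test_matches_explicit_double_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        A = rng.random((n, n))
        S = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(S, 0.0)
        U = rng.random((n, 3))
        brute = 0.5 * sum(
            S[i, j] * np.sum((U[i] - U[j]) ** 2) for i in range(n) for j in range(n)
        )
        assert laplacian_quadratic(U, sp.csr_matrix(S)) == pytest.approx(brute, abs=1e-10)


class TestObjectiveValue:
    def test_zero_factors_leave_weighted_target(self):
        R = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.5]]))
        U = np.zeros((2, 2))
        V = np.zeros((2, 2))
        obj = objective_value(U, V, R, weights=W1)
        assert obj == pytest.approx(1.0**2 + 0.5**2)

    def test_exact_fit_is_zero(self):
        R = sp.csr_matrix(np.array([[1.0]]))
        assert objective_value(np.array([[1.0]]), np.array([[1.0]]), R, weights=W1) == 0.0

    def test_one_by_one_residual(self):
        R = sp.csr_matrix(np.array([[1.0]]))
        obj = objective_value(np.array([[0.5]]), np.array([[1.0]]), R, weights=W1)
        assert obj == pytest.approx(0.25)

    def test_overlapping_R_and_Q_rejected(self):
        R = sp.csr_matrix(np.array([[1.0]]))
        Q = sp.csr_matrix(np.array([[0.5]]))
        with pytest.raises(ValueError, match="overlap"):
            objective_value(np.ones((1, 1)), np.ones((1, 1)), R, Q=Q)


def _als_nnls(M, rank, n_iter=500, seed=0):
    """Independent oracle: alternating NNLS for min ||M - U V^T||_F^2."""
    rng = np.random.default_rng(seed)
    n, m = M.shape
    U = rng.random((n, rank))
    V = rng.random((m, rank))
    for _ in range(n_iter):
        for i in range(n):
            U[i], _ = nnls(V, M[i])
        for j in range(m):
            V[j], _ = nnls(U, M[:, j])
    return U, V


class TestFit:
    def test_empty_problem_collapses_to_zero(self):
        R = sp.csr_matrix((3, 2))
        model = fit(R, rank=2, alpha=0.0, beta=0.0, gamma=0.0, max_iter=50, seed=0)
        assert model.history[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(predict_scores(model), 0.0, atol=1e-6)

    def test_reduction_matches_independent_nnls_factorization(self):
        # beta=gamma=0, w==1 over all cells: the problem is plain
        # nonnegative factorization of R+Q; compare achieved objectives
        rng = np.random.default_rng(3)
        M = rng.random((5, 5))
        model = fit(
            sp.csr_matrix(M), weights=W1, rank=2, alpha=0.0, beta=0.0, gamma=0.0,
            max_iter=4000, tol=1e-14, seed=1,
        )
        U0, V0 = _als_nnls(M, rank=2)
        oracle_obj = np.linalg.norm(M - U0 @ V0.T) ** 2
        assert model.history[-1] <= oracle_obj * 1.05 + 1e-8

    def test_seed_determinism_bitwise(self):
        R = sp.random(20, 10, density=0.2, random_state=7, format="csr")
        R.data[:] = 1.0
        m1 = fit(R, rank=3, beta=0.0, gamma=0.0, max_iter=40, seed=11)
        m2 = fit(R, rank=3, beta=0.0, gamma=0.0, max_iter=40, seed=11)
        assert m1.history == m2.history
        assert np.array_equal(m1.U, m2.U) and np.array_equal(m1.V, m2.V)

    def test_nonnegativity_and_monotone_history(self):
        rng = np.random.default_rng(5)
        R = sp.csr_matrix((rng.random((15, 12)) > 0.8).astype(float))
        C = np.clip(rng.random((15, 15)), 0, 1)
        C = (C + C.T) / 2
        T = np.clip(rng.random((12, 12)), 0, 1)
        T = (T + T.T) / 2
        model = fit(
            R, C=sp.csr_matrix(C), T=sp.csr_matrix(T), rank=3,
            alpha=0.05, beta=0.01, gamma=0.01, max_iter=150, seed=2,
        )
        assert np.all(model.U >= 0) and np.all(model.V >= 0)
        h = np.asarray(model.history)
        assert np.all(np.diff(h) <= 1e-9 * np.maximum(h[:-1], 1.0))

    def test_history_objective_recomputable(self):
        # final history entry equals an independent objective evaluation
        R = sp.random(10, 8, density=0.3, random_state=1, format="csr")
        R.data[:] = 1.0
        w = WeightScheme(1.0, 0.5, 0.01)
        model = fit(R, weights=w, rank=2, alpha=0.1, beta=0.0, gamma=0.0, max_iter=30, seed=4)
        obj = objective_value(model.U, model.V, R, weights=w, alpha=0.1)
        assert obj == pytest.approx(model.history[-1], rel=1e-10)

    def test_missing_graph_with_positive_penalty_rejected(self):
        R = sp.csr_matrix(np.eye(3))
        with pytest.raises(ValueError, match="similarity graph"):
            fit(R, beta=0.1, gamma=0.0, rank=1)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            fit(sp.csr_matrix(np.eye(2)), rank=0)


class TestPredictAndRank:
    def test_scores_are_nonnegative_inner_products(self):
        R = sp.random(12, 9, density=0.3, random_state=0, format="csr")
        R.data[:] = 1.0
        model = fit(R, rank=2, beta=0.0, gamma=0.0, max_iter=50, seed=3)
        P = predict_scores(model)
        assert np.all(P >= 0)
        assert P == pytest.approx(model.U @ model.V.T)

    def test_ranking_order_and_ties(self):
        P = np.array([[0.9, 0.1, 0.5], [0.5, 0.5, 0.1]])
        ranked = rank_targets(P, 0, prot_index=["a", "b", "c"])
        assert [name for name, _ in ranked] == ["a", "c", "b"]
        tied = rank_targets(P, 1, prot_index=["a", "b", "c"])
        assert [name for name, _ in tied] == ["a", "b", "c"]  # tie -> index order

    def test_mask_known_removes_training_positives(self):
        P = np.array([[0.9, 0.8, 0.1]])
        R = sp.csr_matrix(np.array([[1.0, 0.0, 0.0]]))
        ranked = rank_targets(P, 0, prot_index=["a", "b", "c"], mask_known=True, R=R)
        assert [name for name, _ in ranked] == ["b", "c"]

    def test_unknown_chemical_raises(self):
        with pytest.raises(KeyError):
            rank_targets(np.ones((1, 2)), "nope", chem_index=["drug"], prot_index=["a", "b"])


class TestSimilarityGraph:
    def test_asymmetric_input_symmetrized_with_warning(self):
        S = sp.csr_matrix(np.array([[0.0, 0.8], [0.0, 0.0]]))
        with pytest.warns(UserWarning, match="symmetrized"):
            g = SimilarityGraph(S)
        assert g.S[0, 1] == pytest.approx(0.4)
        assert g.S[1, 0] == pytest.approx(0.4)

    def test_self_loops_removed_and_degrees_consistent(self):
        S = sp.csr_matrix(np.array([[0.5, 0.3], [0.3, 0.5]]))
        g = SimilarityGraph(S)
        assert g.S.diagonal().sum() == 0.0
        assert g.degrees == pytest.approx([0.3, 0.3])

    def test_out_of_range_entries_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            SimilarityGraph(sp.csr_matrix(np.array([[0.0, 1.5], [1.5, 0.0]])))
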