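"""Weighted imputed neighborhood-regularized one-class collaborative filtering.

Given an observed chemical-protein interaction matrix ``R`` (n x m, positive
entries only), an optional imputation matrix ``Q`` of structure-derived
putative positives disjoint from ``R``, and chemical-chemical / protein-
protein similarity graphs ``C`` and ``T``, the solver finds nonnegative
low-rank factors U (n x r) and V (m x r) minimizing

    sum_{i,j} w_ij (R_ij + Q_ij - U_i . V_j)^2
      + alpha (||U||_F^2 + ||V||_F^2)
      + beta  tr(U^T (D_C - C) U)
      + gamma tr(V^T (D_T - T) V)

where the sum runs over *all* cells with class-dependent weights: ``w_obs``
on observed entries, ``w_imp`` on imputed entries, ``w_zero`` on the
remaining unobserved cells (whose target is 0, or a uniform imputation value
in the baseline mode).  The Laplacian terms pull similar chemicals
(proteins) toward similar latent factors.  Predicted interaction scores are
P = U V^T.

The optimizer uses multiplicative updates derived from the objective's
gradient split into nonnegative parts (the graph-regularized weighted NMF
scheme), which keeps the factors nonnegative and the objective monotonically
non-increasing.  The dense low-weight background is never materialized: all
dense contractions reduce to rank-r Gram products plus sparse corrections on
the observed/imputed pattern, so one iteration costs
O(nnz * r + (n + m) * r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .activity import InteractionMatrix
from .screen import ImputationNetwork, UniformImputation

__all__ = [
    "SimilarityGraph",
    "WeightScheme",
    "FactorModel",
    "laplacian_quadratic",
    "objective_value",
    "fit",
    "predict_scores",
    "rank_targets",
]

_EPS = 1e-12


class SimilarityGraph:
    """Symmetric similarity graph with entries in [0, 1] plus its degrees.

    Input matrices are symmetrized as (S + S^T)/2 and self-loops removed;
    ``degrees`` holds the diagonal of the degree matrix D used in the
    Laplacian penalty tr(U^T (D - S) U).
    """

    def __init__(self, S, index: Optional[Sequence[str]] = None, symmetrize: bool = True):
        S = sp.csr_matrix(S, dtype=float)
        if S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        asym = abs(S - S.T).max() if S.nnz else 0.0
        if asym > 1e-8:
            if not symmetrize:
                raise ValueError("similarity matrix is not symmetric")
            warnings.warn("asymmetric similarity matrix symmetrized as (S+S^T)/2", stacklevel=2)
        S = (S + S.T) * 0.5
        S.setdiag(0.0)
        S.eliminate_zeros()
        if S.nnz and (S.data.min() < 0 or S.data.max() > 1 + 1e-9):
            raise ValueError("similarity entries must lie in [0, 1]")
        self.S = S.tocsr()
        self.index = list(index) if index is not None else None
        if self.index is not None and len(self.index) != S.shape[0]:
            raise ValueError("index length does not match matrix size")
        self.degrees = np.asarray(self.S.sum(axis=1)).ravel()

    @property
    def shape(self):
        return self.S.shape


@dataclass(frozen=True)
class WeightScheme:
    """Per-class confidence weights: observed >= imputed >= background."""

    w_obs: float = 1.0
    w_imp: float = 0.5
    w_zero: float = 0.01

    def __post_init__(self) -> None:
        if not (self.w_obs >= self.w_imp >= self.w_zero >= 0):
            raise ValueError(
                f"weights must satisfy w_obs >= w_imp >= w_zero >= 0, got "
                f"({self.w_obs}, {self.w_imp}, {self.w_zero})"
            )
        if self.w_obs <= 0:
            raise ValueError("w_obs must be positive")


@dataclass
class FactorModel:
    """Fitted nonnegative factors and the optimization trace."""

    U: np.ndarray
    V: np.ndarray
    rank: int
    alpha: float
    beta: float
    gamma: float
    weights: WeightScheme
    history: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: Optional[int] = None
    chem_index: Optional[list[str]] = None
    prot_index: Optional[list[str]] = None


def _as_graph(G, n: int, name: str) -> Optional[SimilarityGraph]:
    if G is None:
        return None
    if not isinstance(G, SimilarityGraph):
        G = SimilarityGraph(G)
    if G.shape[0] != n:
        raise ValueError(f"{name} has size {G.shape[0]}, expected {n}")
    return G


def laplacian_quadratic(U: np.ndarray, graph: Union[SimilarityGraph, sp.spmatrix, np.ndarray]) -> float:
    """Graph-Laplacian quadratic form tr(U^T (D - S) U).

    Equals 0.5 * sum_ij S_ij ||U_i - U_j||^2: the smoothness of the factor
    rows over the similarity graph.
    """
    if not isinstance(graph, SimilarityGraph):
        S = sp.csr_matrix(graph, dtype=float)
        if (abs(S - S.T).max() if S.nnz else 0.0) > 1e-8:
            raise ValueError("similarity matrix must be symmetric")
        graph = SimilarityGraph(S)
    U = np.asarray(U, dtype=float)
    if U.shape[0] != graph.shape[0]:
        raise ValueError("factor rows do not match graph size")
    quad = float(np.sum(graph.degrees * np.einsum("ij,ij->i", U, U)) - np.sum(U * (graph.S @ U)))
    return max(quad, 0.0)  # clip tiny negative round-off


class _Problem:
    """Preassembled sparse pattern of observed + imputed cells."""

    def __init__(self, R, Q, weights: WeightScheme, uniform_value: float):
        R = sp.coo_matrix(R, dtype=float)
        n, m = R.shape
        if Q is None:
            Q = sp.coo_matrix((n, m))
        else:
            Q = sp.coo_matrix(Q, dtype=float)
            if Q.shape != (n, m):
                raise ValueError(f"Q shape {Q.shape} does not match R shape {(n, m)}")
        overlap = set(zip(R.row.tolist(), R.col.tolist())) & set(zip(Q.row.tolist(), Q.col.tolist()))
        if overlap:
            raise ValueError(f"R and Q overlap at {len(overlap)} cells, e.g. {next(iter(overlap))}")
        self.n, self.m = n, m
        self.rows = np.concatenate([R.row, Q.row])
        self.cols = np.concatenate([R.col, Q.col])
        self.vals = np.concatenate([R.data, Q.data])
        self.wts = np.concatenate(
            [np.full(R.nnz, weights.w_obs), np.full(Q.nnz, weights.w_imp)]
        )
        self.w0 = weights.w_zero
        self.m0 = uniform_value
        if np.any(self.vals < self.m0):
            raise ValueError("observed/imputed values below the uniform imputation baseline")

    def sparse(self, data: np.ndarray) -> sp.csr_matrix:
        return sp.csr_matrix((data, (self.rows, self.cols)), shape=(self.n, self.m))

    def predicted(self, U: np.ndarray, V: np.ndarray) -> np.ndarray:
        return np.einsum("ij,ij->i", U[self.rows], V[self.cols])


def _objective(
    prob: _Problem,
    U: np.ndarray,
    V: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
    C: Optional[SimilarityGraph],
    T: Optional[SimilarityGraph],
) -> float:
    w0, m0 = prob.w0, prob.m0
    p = prob.predicted(U, V)
    # background term over all cells, then corrected on the sparse pattern
    if w0 > 0 or m0 > 0:
        su = U.sum(axis=0)
        sv = V.sum(axis=0)
        s1 = float(su @ sv)  # sum of P
        s2 = float(np.trace((U.T @ U) @ (V.T @ V)))  # ||P||_F^2
        background = w0 * (prob.n * prob.m * m0 * m0 - 2.0 * m0 * s1 + s2)
        correction = float(np.sum(prob.wts * (prob.vals - p) ** 2 - w0 * (m0 - p) ** 2))
    else:
        background = 0.0
        correction = float(np.sum(prob.wts * (prob.vals - p) ** 2))
    obj = background + correction
    obj += alpha * (float(np.sum(U * U)) + float(np.sum(V * V)))
    if beta > 0 and C is not None:
        obj += beta * laplacian_quadratic(U, C)
    if gamma > 0 and T is not None:
        obj += gamma * laplacian_quadratic(V, T)
    return obj


def objective_value(
    U: np.ndarray,
    V: np.ndarray,
    R,
    Q=None,
    weights: WeightScheme = WeightScheme(),
    C=None,
    T=None,
    alpha: float = 0.0,
    beta: float = 0.0,
    gamma: float = 0.0,
    uniform_value: float = 0.0,
) -> float:
    """Evaluate the full weighted one-class objective at (U, V)."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if isinstance(Q, UniformImputation):
        uniform_value, Q = Q.value, None
    prob = _Problem(R, Q, weights, uniform_value)
    Cg = _as_graph(C, prob.n, "C") if beta > 0 else None
    Tg = _as_graph(T, prob.m, "T") if gamma > 0 else None
    return _objective(prob, U, V, alpha, beta, gamma, Cg, Tg)


def _coerce_R(R):
    if isinstance(R, InteractionMatrix):
        return R.matrix, R.chem_index, R.prot_index
    return sp.csr_matrix(R, dtype=float), None, None


def _coerce_Q(Q, chem_index, prot_index, shape):
    """Q may be a sparse matrix, an ImputationNetwork (needs key indices),
    a UniformImputation scalar, or None."""
    if Q is None or sp.issparse(Q) or isinstance(Q, np.ndarray):
        return Q, 0.0
    if isinstance(Q, UniformImputation):
        return None, Q.value
    if isinstance(Q, ImputationNetwork):
        if chem_index is None or prot_index is None:
            raise ValueError("ImputationNetwork Q requires R given as InteractionMatrix")
        cpos = {c: i for i, c in enumerate(chem_index)}
        ppos = {p: j for j, p in enumerate(prot_index)}
        rows, cols, vals = [], [], []
        for (chem, prot), (value, _weight) in Q.items():
            if chem in cpos and prot in ppos:
                rows.append(cpos[chem])
                cols.append(ppos[prot])
                vals.append(value)
        return sp.csr_matrix((vals, (rows, cols)), shape=shape), 0.0
    raise TypeError(f"unsupported Q type {type(Q)!r}")


def fit(
    R,
    Q=None,
    C=None,
    T=None,
    weights: WeightScheme = WeightScheme(),
    rank: int = 100,
    alpha: float = 0.1,
    beta: float = 0.1,
    gamma: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: Optional[int] = None,
) -> FactorModel:
    """Fit nonnegative factors by multiplicative updates on the objective.

    Parameters
    ----------
    R : sparse matrix or InteractionMatrix
        Observed positive associations (values in (0, 1]).
    Q : sparse matrix, ImputationNetwork, UniformImputation, or None
        Structure-screen imputations disjoint from R, or the implicit
        uniform-imputation baseline.
    C, T : SimilarityGraph or sparse matrix, optional
        Chemical-chemical and protein-protein similarity graphs for the
        neighborhood (Laplacian) penalties; required when beta/gamma > 0.
    weights : WeightScheme
        Class-dependent confidence weights.
    rank : int
        Latent dimension r >= 1.
    alpha, beta, gamma : float
        Frobenius and graph-regularization strengths, all >= 0.
    max_iter, tol : iteration cap and relative-objective-change stopping rule.
    seed : RNG seed for the random nonnegative initialization.

    Returns a :class:`FactorModel` whose ``history`` of objective values is
    non-increasing.  Identical seeds give bitwise-identical traces.
    """
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if min(alpha, beta, gamma) < 0:
        raise ValueError("hyperparameters must be nonnegative")
    Rmat, chem_index, prot_index = _coerce_R(R)
    n, m = Rmat.shape
    Qmat, uniform_value = _coerce_Q(Q, chem_index, prot_index, (n, m))
    prob = _Problem(Rmat, Qmat, weights, uniform_value)
    Cg = _as_graph(C, n, "C")
    Tg = _as_graph(T, m, "T")
    if beta > 0 and Cg is None:
        raise ValueError("beta > 0 requires the chemical similarity graph C")
    if gamma > 0 and Tg is None:
        raise ValueError("gamma > 0 requires the protein similarity graph T")

    rng = np.random.default_rng(seed)
    mean_r = prob.vals.mean() if len(prob.vals) else 0.0
    scale = np.sqrt(max(mean_r, _EPS) / rank)
    U = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
    V = rng.uniform(0.1, 1.0, size=(m, rank)) * scale

    w0, m0 = prob.w0, prob.m0
    # sparse numerator data is constant across iterations: w_ij * target_ij
    # minus the background w0 * m0 already accounted for by the Gram term
    num_data = prob.wts * prob.vals - w0 * m0
    dw = prob.wts - w0  # nonnegative by the weight-scheme invariant

    history = [_objective(prob, U, V, alpha, beta, gamma, Cg, Tg)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # --- update U ---
        p = prob.predicted(U, V)
        Snum = prob.sparse(num_data)
        num = Snum @ V
        if w0 > 0 and m0 > 0:
            num += w0 * m0 * np.outer(np.ones(n), V.sum(axis=0))
        den = U @ (V.T @ V) * w0 + prob.sparse(dw * p) @ V + alpha * U
        if beta > 0:
            num += beta * (Cg.S @ U)
            den += beta * (Cg.degrees[:, None] * U)
        U = U * (num / np.maximum(den, _EPS))

        # --- update V ---
        p = prob.predicted(U, V)
        num = Snum.T @ U
        if w0 > 0 and m0 > 0:
            num += w0 * m0 * np.outer(np.ones(m), U.sum(axis=0))
        den = V @ (U.T @ U) * w0 + prob.sparse(dw * p).T @ U + alpha * V
        if gamma > 0:
            num += gamma * (Tg.S @ V)
            den += gamma * (Tg.degrees[:, None] * V)
        V = V * (num / np.maximum(den, _EPS))

        obj = _objective(prob, U, V, alpha, beta, gamma, Cg, Tg)
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective became non-finite at iteration {it}")
        history.append(obj)
        prev = history[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
        if prev == 0.0:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"solver did not converge within {max_iter} iterations "
            f"(last relative change {abs(history[-2] - history[-1]) / max(history[-2], _EPS):.2e})",
            stacklevel=2,
        )
    return FactorModel(
        U=U,
        V=V,
        rank=rank,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        weights=weights,
        history=history,
        converged=converged,
        n_iter=it,
        seed=seed,
        chem_index=chem_index,
        prot_index=prot_index,
    )


def predict_scores(model: FactorModel) -> np.ndarray:
    """Dense score matrix P = U V^T (nonnegative elementwise)."""
    return model.U @ model.V.T


def rank_targets(
    P: np.ndarray,
    chemical_key: Union[str, int],
    chem_index: Optional[Sequence[str]] = None,
    prot_index: Optional[Sequence[str]] = None,
    mask_known: bool = False,
    R=None,
) -> list[tuple[str, float]]:
    """Proteins ranked by descending predicted score for one chemical.

    Ties break by protein index order (stable sort).  With ``mask_known``
    the chemical's training positives in ``R`` are removed from the list.
    """
    if isinstance(chemical_key, str):
        if chem_index is None:
            raise ValueError("chem_index required to look up a chemical by key")
        try:
            i = list(chem_index).index(chemical_key)
        except ValueError:
            raise KeyError(f"unknown chemical {chemical_key!r}") from None
    else:
        i = int(chemical_key)
        if not 0 <= i < P.shape[0]:
            raise KeyError(f"chemical row {i} outside score matrix")
    scores = np.asarray(P)[i]
    names = list(prot_index) if prot_index is not None else list(range(P.shape[1]))
    known: set[int] = set()
    if mask_known:
        if R is None:
            raise ValueError("mask_known requires R")
        Rrow = sp.csr_matrix(R.matrix if isinstance(R, InteractionMatrix) else R)[i]
        known = set(Rrow.indices.tolist())
    order = np.argsort(-scores, kind="stable")
    return [(names[j], float(scores[j])) for j in order if j not in known]
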