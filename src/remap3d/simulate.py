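"""Seeded synthetic-data generators for every input class the toolkit
consumes.

The interaction generator draws block-structured nonnegative factors,
treats the top-density fraction of their product as the true positive
associations, reveals most of them as the observed matrix R, hides a
held-out fraction, hands a subset of the hidden positives to the
"structure screen" imputation matrix Q, and derives the chemical and
protein similarity graphs from cosine similarity of the true factor rows.
This emulates the modelling assumption the solver rests on — that chemical
and protein space are low-rank — together with similarity graphs that are
informative about the latent structure, which is what graph regularization
exploits.  It deliberately does not emulate assay noise heterogeneity,
database biases, or the redundancy of real compound series; see the
methods note for what passing on these fixtures does and does not show.

Dose-response and expression generators add seeded Gaussian noise to the
closed-form curve / a Normal(8, 1) log2 expression background with a mean
shift in differentially expressed genes.

All generators are pure functions of their configuration: the same seed
reproduces outputs bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .doseresponse import DoseResponseCurve, hill_response, sigmoid_response
from .solver import SimilarityGraph

__all__ = [
    "SimulationConfig",
    "SimulatedInteractions",
    "simulate_interaction_data",
    "holdout_auc",
    "half_log_doses",
    "simulate_dose_response",
    "simulate_expression",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the interaction-network generator.

    Defaults give a 200 x 100 problem of rank 5 with 5% positive density
    and a 20% holdout — small enough for second-scale fits, structured
    enough that graph-regularized recovery of held-out positives is
    informative.
    """

    seed: int = 42
    n_chem: int = 200
    n_prot: int = 100
    rank: int = 5
    density: float = 0.05
    n_blocks: int = 5
    noise_sd: float = 0.0
    holdout_fraction: float = 0.2
    q_fraction: float = 0.5  # share of held-out positives revealed to Q

    def __post_init__(self) -> None:
        if self.rank > min(self.n_chem, self.n_prot):
            raise ValueError("rank must not exceed min(n_chem, n_prot)")
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in [0, 1)")
        if self.n_blocks < 1 or self.n_blocks > self.rank:
            raise ValueError("n_blocks must lie in [1, rank]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


class SimulatedInteractions(NamedTuple):
    R: sp.csr_matrix
    Q: sp.csr_matrix
    C: SimilarityGraph
    T: SimilarityGraph
    truth: np.ndarray
    holdout: list[tuple[int, int]]  # hidden positives kept for evaluation
    q_pairs: list[tuple[int, int]]  # hidden positives revealed to Q
    U_true: np.ndarray
    V_true: np.ndarray


def _block_factors(rng: np.random.Generator, n: int, rank: int, n_blocks: int) -> np.ndarray:
    blocks = np.arange(n) % n_blocks
    F = 0.2 * rng.random((n, rank))
    F[np.arange(n), blocks % rank] += 1.0
    return F


def _cosine_graph(F: np.ndarray) -> SimilarityGraph:
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    G = (F / norms) @ (F / norms).T
    np.fill_diagonal(G, 0.0)
    G = np.clip(G, 0.0, 1.0)
    G[G < 0.05] = 0.0  # sparsify negligible similarities
    return SimilarityGraph(sp.csr_matrix(G))


def simulate_interaction_data(config: SimulationConfig = SimulationConfig()) -> SimulatedInteractions:
    """Generate (R, Q, C, T, truth, holdout) under a planted low-rank model."""
    rng = np.random.default_rng(config.seed)
    U = _block_factors(rng, config.n_chem, config.rank, config.n_blocks)
    V = _block_factors(rng, config.n_prot, config.rank, config.n_blocks)
    truth = U @ V.T
    scores = truth + (rng.normal(0.0, config.noise_sd, truth.shape) if config.noise_sd else 0.0)
    n_pos = int(round(config.density * truth.size))
    if n_pos < 1:
        raise ValueError("density too low: no positive associations")
    flat = np.argsort(scores, axis=None)[::-1][:n_pos]
    pos = [(int(i), int(j)) for i, j in zip(*np.unravel_index(flat, truth.shape))]

    n_hold = int(round(config.holdout_fraction * n_pos))
    hold_idx = rng.choice(n_pos, size=n_hold, replace=False)
    hold_set = {pos[i] for i in hold_idx}
    observed = [p for p in pos if p not in hold_set]

    n_q = int(round(config.q_fraction * n_hold))
    hold_list = sorted(hold_set)
    q_idx = rng.choice(n_hold, size=n_q, replace=False) if n_hold else np.array([], dtype=int)
    q_pairs = sorted(hold_list[i] for i in q_idx)
    eval_holdout = sorted(hold_set - set(q_pairs))

    def _mat(pairs: Sequence[tuple[int, int]]) -> sp.csr_matrix:
        if not pairs:
            return sp.csr_matrix((config.n_chem, config.n_prot))
        rows, cols = zip(*pairs)
        return sp.csr_matrix(
            (np.ones(len(pairs)), (rows, cols)), shape=(config.n_chem, config.n_prot)
        )

    return SimulatedInteractions(
        R=_mat(observed),
        Q=_mat(q_pairs),
        C=_cosine_graph(U),
        T=_cosine_graph(V),
        truth=truth,
        holdout=eval_holdout,
        q_pairs=q_pairs,
        U_true=U,
        V_true=V,
    )


def holdout_auc(
    sim: SimulatedInteractions,
    rank: Optional[int] = None,
    alpha: float = 0.1,
    beta: float = 0.01,
    gamma: float = 0.01,
    n_negatives: int = 2000,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Held-out-positive AUC of a fit on a simulated benchmark.

    Fits the solver on (R, Q, C, T), scores the hidden positives that were
    not revealed to Q against ``n_negatives`` seeded-sampled true-negative
    cells, and returns the ROC AUC.

    The default graph-penalty strength here is 0.01, not the solver's 0.1:
    the unnormalized Laplacian penalty scales with graph degree, and the
    generator's cosine graphs are dense (typical degree tens), so the
    penalty must stay small relative to w_obs/degree or it dominates the
    data term and flattens the factors.  Genome-scale similarity networks
    are orders of magnitude sparser, where larger values are harmless.
    """
    from sklearn.metrics import roc_auc_score

    from .solver import fit as _fit, predict_scores

    model = _fit(
        sim.R,
        Q=sim.Q,
        C=sim.C,
        T=sim.T,
        rank=rank if rank is not None else sim.U_true.shape[1],
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
        **fit_kwargs,
    )
    P = predict_scores(model)
    pos = set(map(tuple, np.argwhere(_positive_mask(sim))))
    rng = np.random.default_rng(seed)
    negatives = []
    n, m = sim.truth.shape
    while len(negatives) < n_negatives:
        i, j = int(rng.integers(n)), int(rng.integers(m))
        if (i, j) not in pos:
            negatives.append((i, j))
    y = np.r_[np.ones(len(sim.holdout)), np.zeros(len(negatives))]
    s = np.array([P[i, j] for i, j in list(sim.holdout) + negatives])
    return float(roc_auc_score(y, s))


def _positive_mask(sim: SimulatedInteractions) -> np.ndarray:
    """All true-positive cells (observed + held out + Q)."""
    mask = np.asarray((sim.R + sim.Q).todense()) > 0
    for i, j in sim.holdout:
        mask[i, j] = True
    return mask


def half_log_doses(top: float = 100.0, n: int = 10) -> np.ndarray:
    """Half-log (10^0.5-fold) serial dilution from ``top`` µM, ascending."""
    return top * 10.0 ** (-0.5 * np.arange(n))[::-1]


def simulate_dose_response(
    model: str,
    params: dict,
    doses: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: Optional[int] = None,
    time_zero_count: Optional[float] = None,
) -> list[DoseResponseCurve]:
    """Noisy dose-response curves from the Hill or sigmoid closed form.

    ``model`` is ``"hill"`` (params background, signal, kd) or ``"sigmoid"``
    (params A, B, C, D).  Default doses: 10-point half-log series from
    100 µM.  Gaussian noise of sd ``noise_sd`` is added per replicate.
    """
    x = np.asarray(doses if doses is not None else half_log_doses(), dtype=float)
    if model == "hill":
        y0 = hill_response(x, **params)
    elif model == "sigmoid":
        y0 = sigmoid_response(x, **params)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'hill' or 'sigmoid'")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_replicates):
        y = y0 + (rng.normal(0.0, noise_sd, x.shape) if noise_sd else 0.0)
        curves.append(
            DoseResponseCurve(doses=tuple(x), responses=tuple(y), time_zero_count=time_zero_count)
        )
    return curves


def simulate_expression(
    n_genes: int = 1000,
    n_sensitive: int = 20,
    n_resistant: int = 20,
    n_de_genes: int = 0,
    effect_size: float = 0.0,
    seed: Optional[int] = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, str], set[str]]:
    """Log2 expression matrix with a planted mean shift in DE genes.

    Returns (genes x cell lines DataFrame, cell-line label map, set of true
    differentially expressed genes).  DE genes are shifted upward by
    ``effect_size`` in the sensitive group.
    """
    if n_de_genes > n_genes:
        raise ValueError("n_de_genes must not exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{k:05d}" for k in range(n_genes)]
    cells = [f"S{k:03d}" for k in range(n_sensitive)] + [f"R{k:03d}" for k in range(n_resistant)]
    X = rng.normal(baseline_mean, baseline_sd, (n_genes, n_sensitive + n_resistant))
    de = rng.choice(n_genes, size=n_de_genes, replace=False)
    X[np.ix_(de, np.arange(n_sensitive))] += effect_size
    labels = {c: ("sensitive" if c.startswith("S") else "resistant") for c in cells}
    return pd.DataFrame(X, index=genes, columns=cells), labels, {genes[i] for i in de}
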