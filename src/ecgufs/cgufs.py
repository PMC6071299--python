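"""Consensus-guided unsupervised feature selection (CGUFS).

The method alternates two steps to minimise

    alpha * ||B - H* C||_F^2  +  ||X^T Z - H* G||_F^2  +  beta * ||Z||_{2,1}

over the consensus partition H* (samples x K indicator), the center
matrices C and G, and the feature-selection matrix Z (genes x K):

1. *Consensus step* — with Z fixed, the first two terms equal the
   within-cluster sum of squares of K-means on the augmented matrix
   U = [sqrt(alpha) * B | X^T Z], so H*, C and G are updated by one
   K-means pass on U, warm-started from the current partition.
2. *Z step* — with H* and G fixed, the row-sparse l2,1 penalty is
   handled by iteratively reweighted least squares: solve
   (X X^T + beta * F) Z = X H* G where F = diag(1 / (2 ||Z_i.||_2))
   is built from the previous Z (row norms clamped at eps).

Each gene's weight is the l2 norm of its row of Z; rows driven to zero
by the penalty mark uninformative genes, large rows mark genes that
discriminate the (pseudo-label) sample clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .consensus import (
    BasicClusteringSet,
    CenterMatrix,
    ClusterIndicator,
    generate_basic_clusterings,
    run_kmeans,
)
from .preprocess import ExpressionMatrix

logger = logging.getLogger("ecgufs")

__all__ = [
    "FeatureSelectionState",
    "AugmentedMatrix",
    "GeneWeights",
    "RankedGeneList",
    "build_augmented",
    "consensus_step",
    "update_Z",
    "objective_value",
    "run_cgufs",
    "gene_weights",
    "rank_genes",
    "EPS_ROW_NORM",
]

#: clamp on row norms of Z inside the IRLS reweighting matrix F; the
#: update divides by ||Z_i.||_2 which is undefined at zero.
EPS_ROW_NORM = 1e-8


@dataclass
class FeatureSelectionState:
    """Converged (or last-iterate) state of the alternating optimisation."""

    Z: np.ndarray
    G: np.ndarray
    alpha: float
    beta: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def F_diagonal(self) -> np.ndarray:
        """Diagonal of the IRLS reweighting matrix for the current Z."""
        norms = np.maximum(np.linalg.norm(self.Z, axis=1), EPS_ROW_NORM)
        return 1.0 / (2.0 * norms)


@dataclass
class AugmentedMatrix:
    """U = [scale * B | X^T Z] with the block boundary recorded.

    ``scale`` is sqrt(alpha) by default so that squared Euclidean
    distances between rows of U reproduce alpha * ||B - H* C||^2 in the
    clustering objective; strict mode uses scale = alpha instead.
    """

    U: np.ndarray
    boundary: int
    alpha: float
    scale: float


@dataclass
class GeneWeights:
    """Nonnegative per-gene importance scores, aligned with gene_ids."""

    w: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")
        if len(self.gene_ids) != self.w.size:
            raise ValueError("gene_ids length must match weights")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")


@dataclass
class RankedGeneList:
    """Gene identifiers in descending-weight order with aligned weights."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != self.weights.size:
            raise ValueError("gene_ids length must match weights")
        if np.any(np.diff(self.weights) > 0):
            raise ValueError("weights must be non-increasing")

    def top(self, k: int) -> list[str]:
        if k > len(self.gene_ids):
            raise ValueError(f"k={k} exceeds list length {len(self.gene_ids)}")
        return self.gene_ids[:k]

    def __len__(self) -> int:
        return len(self.gene_ids)


def build_augmented(
    B: BasicClusteringSet,
    X: ExpressionMatrix,
    Z: np.ndarray,
    alpha: float,
    linear_alpha_u: bool = False,
) -> AugmentedMatrix:
    """Assemble the augmented matrix U = [sqrt(alpha)*B | X^T Z].

    With the sqrt(alpha) scaling, K-means on the rows of U minimises
    alpha*||B - H*C||^2 + ||X^T Z - H*G||^2 exactly. ``linear_alpha_u``
    switches to the literal alpha*B scaling.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (X.n_genes, B.K):
        raise ValueError(
            f"Z has shape {Z.shape}, expected ({X.n_genes}, {B.K})"
        )
    if B.n_samples != X.n_samples:
        raise ValueError("B and X disagree on the number of samples")
    scale = alpha if linear_alpha_u else float(np.sqrt(alpha))
    U = np.hstack([scale * B.B, X.values.T @ Z])
    return AugmentedMatrix(U=U, boundary=B.B.shape[1], alpha=alpha, scale=scale)


def consensus_step(
    U: AugmentedMatrix,
    K: int,
    seed: int,
    init_indicator: ClusterIndicator | None = None,
    restarts: int = 1,
) -> tuple[ClusterIndicator, CenterMatrix, np.ndarray]:
    """K-means on the rows of U; split the centers at the block boundary.

    Returns the consensus indicator H*, the center matrix C over the B
    block (scaled back to B's units), and the mapping matrix G — the
    trailing K columns of the centers, aligned with the X^T Z block.

    When ``init_indicator`` is given the run is warm-started from that
    partition's centers (a single Lloyd descent), which guarantees the
    clustering objective does not increase across outer iterations.
    """
    rows = U.U
    if init_indicator is not None:
        H = init_indicator.matrix
        sizes = H.sum(axis=0)
        if np.any(sizes == 0):
            raise ValueError("warm-start indicator has an empty cluster")
        centers0 = (H.T @ rows) / sizes[:, None]
        Hstar, centers = run_kmeans(rows, K, seed=seed, init=centers0)
    else:
        Hstar, centers = run_kmeans(rows, K, seed=seed, restarts=restarts)
    left = centers.centers[:, : U.boundary]
    G = centers.centers[:, U.boundary :]
    C = left / U.scale if U.scale > 0 else np.zeros_like(left)
    return Hstar, CenterMatrix(C, centers.inertia), G


def update_Z(
    X: ExpressionMatrix,
    Hstar: ClusterIndicator,
    G: np.ndarray,
    beta: float,
    Z_prev: np.ndarray,
    eps: float = EPS_ROW_NORM,
    xxt: np.ndarray | None = None,
) -> np.ndarray:
    """One IRLS update of the feature-selection matrix.

    Solves (X X^T + beta*F) Z = X H* G where F is diagonal with entries
    1/(2*max(||Z_prev_i.||_2, eps)). For beta=0 the system reduces to
    the normal equations of ||X^T Z - H* G||_F, which are solved in the
    minimum-norm least-squares sense (X X^T is singular whenever there
    are more genes than samples).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    G = np.asarray(G, dtype=float)
    target = Hstar.matrix @ G  # s x K
    if beta == 0:
        Z, *_ = np.linalg.lstsq(X.values.T, target, rcond=None)
        return Z
    Z_prev = np.asarray(Z_prev, dtype=float)
    norms = np.maximum(np.linalg.norm(Z_prev, axis=1), eps)
    f_diag = beta / (2.0 * norms)
    A = (X.values @ X.values.T) if xxt is None else xxt.copy()
    A[np.diag_indices_from(A)] += f_diag
    rhs = X.values @ target
    try:
        return scipy.linalg.solve(A, rhs, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
        raise np.linalg.LinAlgError(
            "singular system in the Z update; increase beta or add jitter to X"
        ) from exc


def objective_value(
    B: BasicClusteringSet,
    Hstar: ClusterIndicator,
    C: CenterMatrix,
    X: ExpressionMatrix,
    Z: np.ndarray,
    G: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """alpha*||B - H*C||_F^2 + ||X^T Z - H*G||_F^2 + beta*||Z||_{2,1}."""
    Z = np.asarray(Z, dtype=float)
    consensus = np.linalg.norm(B.B - Hstar.matrix @ C.centers) ** 2
    regression = np.linalg.norm(X.values.T @ Z - Hstar.matrix @ G) ** 2
    sparsity = np.linalg.norm(Z, axis=1).sum()
    return float(alpha * consensus + regression + beta * sparsity)


def gene_weights(Z: np.ndarray, gene_ids: list[str]) -> GeneWeights:
    """Per-gene weights: the l2 norm of each row of Z."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    return GeneWeights(np.linalg.norm(Z, axis=1), list(gene_ids))


def rank_genes(W: GeneWeights) -> RankedGeneList:
    """Sort genes into descending weight order; ties keep input order."""
    order = np.argsort(-W.w, kind="stable")
    return RankedGeneList(
        [W.gene_ids[i] for i in order], W.w[order]
    )


def run_cgufs(
    X: ExpressionMatrix,
    K: int = 6,
    r: int = 100,
    alpha: float = 1e4,
    beta: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    restarts: int = 10,
    linear_alpha_u: bool = False,
    basic_clusterings: BasicClusteringSet | None = None,
) -> tuple[GeneWeights, FeatureSelectionState, ClusterIndicator]:
    """Full alternating optimisation on a preprocessed expression matrix.

    X should have z-scored gene rows (see :func:`ecgufs.preprocess.zscore_genes`)
    for well-conditioned convergence. The consensus indicator H* is
    initialised by consensus clustering of B alone, Z by uniform(0, 1)
    entries; the loop alternates the consensus step and the Z update
    until the relative objective change drops below ``tol`` or
    ``max_iter`` outer iterations are reached (the latter emits a
    warning, not an error).

    ``basic_clusterings`` can inject a precomputed B (it must match X's
    samples); by default r fresh basic clusterings are generated.
    """
    ss = np.random.SeedSequence(seed)
    seed_B, seed_H, seed_Z, seed_loop = (
        int(s) % (2**31) for s in ss.generate_state(4)
    )
    if basic_clusterings is None:
        B = generate_basic_clusterings(X, K, r, seed=seed_B, restarts=restarts)
    else:
        B = basic_clusterings
        if B.n_samples != X.n_samples:
            raise ValueError("injected B does not match X's samples")
    # H* init: consensus clustering = K-means on B alone
    H, _ = run_kmeans(B.B, K, seed=seed_H, restarts=restarts)
    rng = np.random.default_rng(seed_Z)
    Z = rng.uniform(0.0, 1.0, size=(X.n_genes, K))
    xxt = X.values @ X.values.T

    trace: list[float] = []
    converged = False
    prev_obj = np.inf
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        U = build_augmented(B, X, Z, alpha, linear_alpha_u=linear_alpha_u)
        H, C, G = consensus_step(U, K, seed=seed_loop, init_indicator=H)
        Z = update_Z(X, H, G, beta, Z, xxt=xxt)
        obj = objective_value(B, H, C, X, Z, G, alpha, beta)
        trace.append(obj)
        if it > 0 and abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
            converged = True
            break
        prev_obj = obj
    if not converged:
        last_change = abs(trace[-2] - trace[-1]) if len(trace) > 1 else np.inf
        warnings.warn(
            f"CGUFS did not converge in {max_iter} iterations "
            f"(last absolute objective change {last_change:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    state = FeatureSelectionState(
        Z=Z, G=G, alpha=alpha, beta=beta,
        objective_trace=trace, converged=converged, n_iter=n_iter,
    )
    return gene_weights(Z, X.gene_ids), state, H
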