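"""Basic clusterings and the K-means engine used throughout.

Consensus clustering combines ``r`` independent "basic" K-means
partitions of the same samples. Each partition is stored as a binary
indicator matrix H (samples x K, one 1 per row) and the r indicators are
stacked horizontally into B (samples x rK), which downstream code
clusters again to obtain the consensus partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import ExpressionMatrix

logger = logging.getLogger("ecgufs")

__all__ = [
    "ClusterIndicator",
    "CenterMatrix",
    "BasicClusteringSet",
    "run_kmeans",
    "generate_basic_clusterings",
]


@dataclass
class ClusterIndicator:
    """Binary samples x K matrix with exactly one 1 per row."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("indicator must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("indicator entries must be 0/1")
        if not np.all(self.matrix.sum(axis=1) == 1):
            raise ValueError("every indicator row must sum to exactly 1")
        s, k = self.matrix.shape
        if k < 1:
            raise ValueError("K must be >= 1")
        if s < k:
            logger.info("indicator has fewer samples (%d) than clusters (%d)", s, k)
        self.matrix = self.matrix.astype(float)

    @classmethod
    def from_labels(cls, labels: np.ndarray, K: int) -> "ClusterIndicator":
        labels = np.asarray(labels, dtype=int)
        mat = np.zeros((labels.size, K))
        mat[np.arange(labels.size), labels] = 1.0
        return cls(mat)

    @property
    def labels(self) -> np.ndarray:
        return self.matrix.argmax(axis=1)

    @property
    def n_clusters(self) -> int:
        return self.matrix.shape[1]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(int)


@dataclass
class CenterMatrix:
    """K x d matrix of cluster centers; ``inertia`` is the within-cluster
    sum of squared distances of the fit that produced it."""

    centers: np.ndarray
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2:
            raise ValueError("centers must be 2-D")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")


@dataclass
class BasicClusteringSet:
    """r stacked indicator matrices: B is samples x (r*K)."""

    B: np.ndarray
    r: int
    K: int

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        s, width = self.B.shape
        if width != self.r * self.K:
            raise ValueError(f"B has width {width}, expected r*K = {self.r * self.K}")
        if not np.allclose(self.B.sum(axis=1), self.r):
            raise ValueError("every row of B must sum to r")

    @property
    def n_samples(self) -> int:
        return self.B.shape[0]

    def block(self, i: int) -> ClusterIndicator:
        """The i-th basic clustering (0-based)."""
        return ClusterIndicator(self.B[:, i * self.K : (i + 1) * self.K])


def run_kmeans(
    rows: np.ndarray,
    K: int,
    seed: int,
    max_iter: int = 300,
    restarts: int = 10,
    init: np.ndarray | None = None,
) -> tuple[ClusterIndicator, CenterMatrix]:
    """Hard K-means on the rows of a matrix.

    Best-of-``restarts`` k-means++ runs (Lloyd iterations), deterministic
    for a given ``seed``. When ``init`` (a K x d center matrix) is given,
    a single Lloyd run from those centers is performed instead — used by
    the consensus step to warm-start from the previous partition so the
    outer objective cannot increase. The returned solution never has an
    empty cluster (empty clusters are repaired by relocating the points
    contributing most to the objective).
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("rows must be a 2-D matrix")
    s = rows.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > s:
        raise ValueError(f"cannot form {K} non-empty clusters from {s} samples")
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (K, rows.shape[1]):
            raise ValueError("init centers have wrong shape")
        km = KMeans(n_clusters=K, init=init, n_init=1, max_iter=max_iter,
                    random_state=int(seed) % (2**31))
    else:
        km = KMeans(n_clusters=K, init="k-means++", n_init=restarts,
                    max_iter=max_iter, random_state=int(seed) % (2**31))
    km.fit(rows)
    labels, centers = _repair_empty_clusters(rows, km.labels_, K)
    inertia = float(((rows - centers[labels]) ** 2).sum())
    return ClusterIndicator.from_labels(labels, K), CenterMatrix(centers, inertia)


def _repair_empty_clusters(
    rows: np.ndarray, labels: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Force all K clusters non-empty: move the point farthest from its
    center into each empty cluster (taken from clusters of size > 1),
    then recompute centers. Degenerate ties (e.g. identical rows) fall
    back to any point from the largest cluster."""
    labels = np.asarray(labels, dtype=int).copy()
    for k in range(K):
        if np.any(labels == k):
            continue
        sizes = np.bincount(labels, minlength=K)
        movable = np.flatnonzero(sizes[labels] > 1)
        centers = np.vstack([
            rows[labels == j].mean(axis=0) if sizes[j] else np.zeros(rows.shape[1])
            for j in range(K)
        ])
        dist = ((rows[movable] - centers[labels[movable]]) ** 2).sum(axis=1)
        labels[movable[np.argmax(dist)]] = k
        logger.info("run_kmeans: repaired empty cluster %d", k)
    centers = np.vstack([rows[labels == j].mean(axis=0) for j in range(K)])
    return labels, centers


def generate_basic_clusterings(
    X: ExpressionMatrix,
    K: int,
    r: int,
    seed: int,
    max_iter: int = 300,
    restarts: int = 10,
) -> BasicClusteringSet:
    """r independent K-means clusterings of the samples of X.

    Samples (columns of X) are the points being clustered, over all
    genes. Each clustering draws its initialization from a distinct
    random stream derived from ``seed``; diversity comes from the random
    k-means++ seeding alone. The label permutation of each block is
    irrelevant downstream (B enters only through Euclidean distances).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    samples = X.values.T  # s x g
    child_seeds = np.random.SeedSequence(seed).generate_state(r) % (2**31)
    blocks = []
    for i in range(r):
        ind, _ = run_kmeans(samples, K, seed=int(child_seeds[i]),
                            max_iter=max_iter, restarts=restarts)
        blocks.append(ind.matrix)
    B = np.hstack(blocks)
    return BasicClusteringSet(B=B, r=r, K=K)
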