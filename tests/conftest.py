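"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ecgufs import ExpressionMatrix, GeneLabelSet, SyntheticSpec, generate, zscore_genes


def pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive Mann-Whitney AUC: (#concordant + 0.5 * #tied) / (P * N).

    Independent of the curve-sweep implementation under test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (pos.size * neg.size)


def brute_force_kmeans_2(points: np.ndarray) -> float:
    """Global optimum of the K=2 within-cluster sum of squares by
    enumerating every 2-partition (both clusters non-empty)."""
    n = points.shape[0]
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for grp in (points[~mask], points[mask]):
            if grp.size:
                sse += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 5.0]]),
        ["gA", "gB", "gC"],
        ["s1", "s2"],
    )


@pytest.fixture
def small_labels() -> GeneLabelSet:
    return GeneLabelSet({"gA": 1, "gB": 0, "gC": 1})


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated planted clusters: effect 3 sd, 48 samples in 6 groups."""
    spec = SyntheticSpec(g=120, s=48, K_true=6, n_informative=20,
                         effect=3.0, seed=11)
    X, labels, assignment = generate(spec)
    return X, labels, assignment


@pytest.fixture(scope="session")
def zscored_easy_dataset(easy_dataset):
    X, labels, assignment = easy_dataset
    return zscore_genes(X), labels, assignment
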