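"""The alternating optimisation: augmented matrix, Z update, objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgufs import (
    ClusterIndicator,
    ExpressionMatrix,
    GeneWeights,
    build_augmented,
    consensus_step,
    gene_weights,
    generate_basic_clusterings,
    objective_value,
    rank_genes,
    run_cgufs,
    update_Z,
)
from ecgufs.consensus import BasicClusteringSet
from .conftest import brute_force_kmeans_2


def _matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


def _indicator(labels, K):
    return ClusterIndicator.from_labels(np.asarray(labels), K)


def _basic_set(s, r, K, seed=0):
    rng = np.random.default_rng(seed)
    blocks = [
        _indicator(rng.integers(0, K, size=s), K).matrix for _ in range(r)
    ]
    return BasicClusteringSet(np.hstack(blocks), r=r, K=K)


class TestBuildAugmented:
    def test_shape_and_blocks(self):
        X = _matrix(np.arange(12).reshape(3, 4))
        B = _basic_set(4, r=2, K=2)
        Z = np.ones((3, 2))
        U = build_augmented(B, X, Z, alpha=4.0)
        assert U.U.shape == (4, 2 * 2 + 2)
        # sqrt(alpha) scaling of the clustering block
        np.testing.assert_allclose(U.U[:, :4], 2.0 * B.B)
        np.testing.assert_allclose(U.U[:, 4:], X.values.T @ Z)

    def test_alpha_zero_left_block_vanishes(self):
        X = _matrix(np.arange(6).reshape(3, 2))
        B = _basic_set(2, r=1, K=2)
        U = build_augmented(B, X, np.ones((3, 2)), alpha=0.0)
        np.testing.assert_array_equal(U.U[:, :2], 0.0)

    def test_alpha_one_is_plain_concatenation(self):
        X = _matrix(np.arange(6).reshape(3, 2))
        B = _basic_set(2, r=1, K=2)
        U = build_augmented(B, X, np.ones((3, 2)), alpha=1.0)
        np.testing.assert_array_equal(U.U[:, :2], B.B)

    def test_strict_mode_scales_by_alpha(self):
        X = _matrix(np.arange(6).reshape(3, 2))
        B = _basic_set(2, r=1, K=2)
        U = build_augmented(B, X, np.zeros((3, 2)), alpha=9.0, linear_alpha_u=True)
        np.testing.assert_allclose(U.U[:, :2], 9.0 * B.B)

    def test_dimension_mismatch(self):
        X = _matrix(np.arange(6).reshape(3, 2))
        B = _basic_set(2, r=1, K=2)
        with pytest.raises(ValueError, match="shape"):
            build_augmented(B, X, np.ones((4, 2)), alpha=1.0)


class TestConsensusStep:
    def test_four_row_toy_matches_enumeration(self):
        X = _matrix(np.array([[0.0, 0.1, 5.0, 5.1]]))
        B = _basic_set(4, r=2, K=2, seed=1)
        U = build_augmented(B, X, np.array([[1.0, 0.5]]), alpha=2.0)
        H, C, G = consensus_step(U, K=2, seed=0, restarts=10)
        sse_best = brute_force_kmeans_2(U.U)
        sizes = H.matrix.sum(axis=0)
        centers = np.hstack([U.scale * C.centers, G])
        sse = ((U.U - H.matrix @ centers) ** 2).sum()
        assert sse == pytest.approx(sse_best, abs=1e-10)
        assert sizes.min() >= 1

    def test_alpha_zero_partition_ignores_B(self):
        rng = np.random.default_rng(4)
        X = _matrix(rng.normal(size=(3, 6)))
        Z = rng.uniform(size=(3, 2))
        B1 = _basic_set(6, r=3, K=2, seed=1)
        B2 = _basic_set(6, r=3, K=2, seed=2)
        H1, _, G1 = consensus_step(build_augmented(B1, X, Z, 0.0), 2, seed=0, restarts=5)
        H2, _, G2 = consensus_step(build_augmented(B2, X, Z, 0.0), 2, seed=0, restarts=5)
        np.testing.assert_array_equal(H1.matrix, H2.matrix)
        np.testing.assert_allclose(G1, G2)

    def test_g_rows_align_with_xtz_block(self):
        # s = K distinct rows: every sample its own cluster, G rows equal X^T Z rows
        X = _matrix(np.eye(2) * 3)
        B = _basic_set(2, r=1, K=2, seed=3)
        Z = np.array([[1.0, 2.0], [0.5, 1.5]])
        U = build_augmented(B, X, Z, alpha=1.0)
        H, C, G = consensus_step(U, K=2, seed=0, restarts=5)
        xtz = X.values.T @ Z
        recovered = H.matrix @ G
        np.testing.assert_allclose(recovered, xtz, atol=1e-12)


class TestUpdateZ:
    def test_scalar_fixed_point(self):
        """g=1, s=2, X=[1,1], H*G=[1;1], beta=1: repeated updates converge
        to the analytic stationary point z = 3/4."""
        X = _matrix(np.array([[1.0, 1.0]]))
        H = _indicator([0, 0], 1)
        G = np.array([[1.0]])
        Z = np.array([[0.3]])
        for _ in range(200):
            Z = update_Z(X, H, G, beta=1.0, Z_prev=Z)
        assert Z[0, 0] == pytest.approx(0.75, abs=1e-8)

    def test_beta_zero_satisfies_normal_equations(self):
        rng = np.random.default_rng(8)
        X = _matrix(rng.normal(size=(6, 4)))
        H = _indicator([0, 1, 0, 1], 2)
        G = rng.normal(size=(2, 2))
        Z = update_Z(X, H, G, beta=0.0, Z_prev=np.zeros((6, 2)))
        residual = X.values @ (X.values.T @ Z - H.matrix @ G)
        assert np.abs(residual).max() < 1e-8

    def test_zero_row_clamped_no_nan(self):
        rng = np.random.default_rng(9)
        X = _matrix(rng.normal(size=(3, 5)))
        H = _indicator([0, 1, 0, 1, 0], 2)
        G = rng.normal(size=(2, 2))
        Z_prev = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        Z = update_Z(X, H, G, beta=1.0, Z_prev=Z_prev)
        assert np.all(np.isfinite(Z))

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_satisfies_stationarity(self, seed):
        """Iterating the update with H*, G fixed converges to Z solving
        (X X^T + beta F(Z)) Z = X H* G."""
        rng = np.random.default_rng(seed)
        g, s, K = 4, 6, 2
        X = _matrix(rng.normal(size=(g, s)))
        H = _indicator(rng.integers(0, K, size=s), K)
        G = rng.normal(size=(K, K))
        beta = 0.5
        Z = rng.uniform(size=(g, K))
        for _ in range(20000):
            Z_next = update_Z(X, H, G, beta=beta, Z_prev=Z)
            done = np.abs(Z_next - Z).max() < 1e-13
            Z = Z_next
            if done:
                break
        norms = np.maximum(np.linalg.norm(Z, axis=1), 1e-8)
        F = np.diag(1.0 / (2.0 * norms))
        lhs = (X.values @ X.values.T + beta * F) @ Z
        rhs = X.values @ H.matrix @ G
        assert np.abs(lhs - rhs).max() < 1e-6


class TestObjectiveValue:
    def test_all_zero_is_zero(self):
        X = _matrix(np.zeros((2, 3)))
        B = BasicClusteringSet(np.hstack([_indicator([0, 0, 0], 1).matrix]), 1, 1)
        H = _indicator([0, 0, 0], 1)
        from ecgufs import CenterMatrix
        # B - H*C vanishes when C matches the single indicator column
        val = objective_value(B, H, CenterMatrix(np.ones((1, 1))), X,
                              np.zeros((2, 1)), np.zeros((1, 1)), 1.0, 1.0)
        assert val == 0.0

    def test_matches_elementwise_hand_computation(self):
        rng = np.random.default_rng(3)
        X = _matrix(rng.normal(size=(2, 2)))
        B = _basic_set(2, r=1, K=2, seed=0)
        H = _indicator([0, 1], 2)
        from ecgufs import CenterMatrix
        C = rng.normal(size=(2, 2))
        G = rng.normal(size=(2, 2))
        Z = rng.normal(size=(2, 2))
        alpha, beta = 2.0, 3.0
        # brute-force double loops
        t1 = sum((B.B[i, j] - sum(H.matrix[i, k] * C[k, j] for k in range(2))) ** 2
                 for i in range(2) for j in range(2))
        xtz = X.values.T @ Z
        t2 = sum((xtz[i, j] - sum(H.matrix[i, k] * G[k, j] for k in range(2))) ** 2
                 for i in range(2) for j in range(2))
        t3 = sum(np.sqrt(Z[i, 0] ** 2 + Z[i, 1] ** 2) for i in range(2))
        expected = alpha * t1 + t2 + beta * t3
        got = objective_value(B, H, CenterMatrix(C), X, Z, G, alpha, beta)
        assert got == pytest.approx(expected, rel=1e-12)


class TestWeightsAndRanking:
    def test_row_345(self):
        W = gene_weights(np.array([[3.0, 4.0], [0.0, 0.0]]), ["a", "b"])
        np.testing.assert_allclose(W.w, [5.0, 0.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(6, 4))
        perm = rng.permutation(4)
        a = gene_weights(Z, [f"g{i}" for i in range(6)])
        b = gene_weights(Z[:, perm], [f"g{i}" for i in range(6)])
        np.testing.assert_allclose(a.w, b.w)

    def test_rank_descending_with_stable_ties(self):
        W = GeneWeights(np.array([1.0, 3.0, 2.0, 3.0]), ["a", "b", "c", "d"])
        ranked = rank_genes(W)
        assert ranked.gene_ids == ["b", "d", "c", "a"]

    def test_all_equal_weights_preserve_order(self):
        W = GeneWeights(np.ones(3), ["x", "y", "z"])
        assert rank_genes(W).gene_ids == ["x", "y", "z"]


class TestRunCgufs:
    def test_bit_reproducible(self, zscored_easy_dataset):
        X, _, _ = zscored_easy_dataset
        kw = dict(K=6, r=5, alpha=1e4, beta=1.0, seed=77, max_iter=30)
        W1, s1, H1 = run_cgufs(X, **kw)
        W2, s2, H2 = run_cgufs(X, **kw)
        np.testing.assert_array_equal(W1.w, W2.w)
        np.testing.assert_array_equal(H1.matrix, H2.matrix)
        assert s1.objective_trace == s2.objective_trace

    def test_objective_trace_non_increasing(self, zscored_easy_dataset):
        X, _, _ = zscored_easy_dataset
        _, state, _ = run_cgufs(X, K=6, r=10, alpha=1e4, beta=1.0, seed=5,
                                max_iter=50)
        diffs = np.diff(state.objective_trace)
        assert np.all(diffs <= 1e-9)

    def test_recovers_planted_genes(self, zscored_easy_dataset):
        """Planted discriminative genes occupy the top ranks: median
        ranking AUC over three fit seeds clears 0.9 on separable data."""
        X, labels, _ = zscored_easy_dataset
        from ecgufs import bag_auc
        aucs = [
            bag_auc(run_cgufs(X, K=6, r=20, alpha=1e4, beta=1.0, seed=seed,
                              max_iter=50)[0], labels)
            for seed in (1, 2, 3)
        ]
        assert np.median(aucs) >= 0.9

    def test_nonconvergence_warns_but_returns(self, zscored_easy_dataset):
        X, _, _ = zscored_easy_dataset
        with pytest.warns(RuntimeWarning, match="did not converge"):
            W, state, _ = run_cgufs(X, K=6, r=5, alpha=1e4, beta=1.0,
                                    seed=1, max_iter=1)
        assert not state.converged
        assert np.all(np.isfinite(W.w))

    def test_sqrt_alpha_scale_consistency(self, zscored_easy_dataset):
        """Multiplying alpha by c^2 scales U's left block by c but, with
        Z = 0, leaves the consensus partition unchanged (distances scale
        uniformly)."""
        X, _, _ = zscored_easy_dataset
        B = generate_basic_clusterings(X, K=3, r=4, seed=0)
        Z = np.zeros((X.n_genes, 3))
        U1 = build_augmented(B, X, Z, alpha=1.0)
        U2 = build_augmented(B, X, Z, alpha=4.0)
        H1, _, _ = consensus_step(U1, 3, seed=0, restarts=5)
        H2, _, _ = consensus_step(U2, 3, seed=0, restarts=5)
        np.testing.assert_array_equal(H1.matrix, H2.matrix)
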