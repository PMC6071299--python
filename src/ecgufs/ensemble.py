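"""Bagging ensemble over CGUFS runs (ECGUFS).

A single CGUFS run is sensitive to the random initialisation of the
feature-selection matrix, which destabilises the final gene ranking.
The ensemble draws ``b`` bootstrap bags of ``c`` samples (with
replacement), runs the full CGUFS optimisation on each bag — including
fresh basic clusterings, since bags differ in their sample draw —
scores each bag's ranking by its ROC AUC against the labeled evaluation
genes (a_i), and combines the per-bag weight vectors linearly:

    W_final = sum_i  a_i * W_i

Genes are then ranked by W_final in descending order. An unweighted
mode (all a_i = 1) supports fully label-free use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cgufs import GeneWeights, FeatureSelectionState, RankedGeneList, rank_genes, run_cgufs
from .evaluation import roc_pr_curves
from .preprocess import ExpressionMatrix, GeneLabelSet, zscore_genes

logger = logging.getLogger("ecgufs")

__all__ = [
    "BagResult",
    "bootstrap_bags",
    "bag_auc",
    "run_ecgufs",
    "consensus_gene_set",
]


@dataclass
class BagResult:
    """One bag's draw, fitted gene weights, and ranking AUC a_i."""

    bag_index: int
    sample_draw: np.ndarray  # c drawn sample indices into the source matrix
    weights: GeneWeights
    auc: float
    state: FeatureSelectionState | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC must lie in [0, 1], got {self.auc}")


def _bag_matrix(X: ExpressionMatrix, draw: np.ndarray) -> ExpressionMatrix:
    """Column-subset with replacement; repeats get distinct instance ids."""
    counts: dict[int, int] = {}
    ids = []
    for idx in draw:
        k = counts.get(idx, 0)
        counts[idx] = k + 1
        base = X.sample_ids[idx]
        ids.append(base if k == 0 else f"{base}#{k}")
    return ExpressionMatrix(X.values[:, draw], list(X.gene_ids), ids)


def bootstrap_bags(
    X: ExpressionMatrix, b: int, c: int, seed: int
) -> list[ExpressionMatrix]:
    """Draw b bags of c samples with replacement from X's columns.

    Deterministic per seed; per-bag random streams are split from the
    master seed so b and seed fully determine every draw. A degenerate
    bag whose draws are all the same sample is redrawn (up to 100
    attempts, logged).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if c < 2:
        raise ValueError("c must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(b)
    bags = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for attempt in range(100):
            draw = rng.integers(0, X.n_samples, size=c)
            if np.unique(draw).size > 1:
                break
            logger.info("bag %d: degenerate draw, regenerating (attempt %d)",
                        i, attempt + 1)
        else:
            raise RuntimeError(f"bag {i}: could not draw a non-degenerate bag")
        bags.append(_bag_matrix(X, draw))
    return bags


def bag_auc(W: GeneWeights, labels: GeneLabelSet) -> float:
    """ROC AUC of the descending-weight ranking over the labeled genes."""
    return roc_pr_curves(rank_genes(W), labels).auc


def run_ecgufs(
    X: ExpressionMatrix,
    labels: GeneLabelSet | None,
    K: int = 6,
    r: int = 100,
    alpha: float = 1e4,
    beta: float = 1.0,
    b: int = 20,
    c: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    restarts: int = 10,
    linear_alpha_u: bool = False,
    unweighted: bool = False,
    drop_poor_bags: bool = False,
    standardize_bags: bool = True,
) -> tuple[GeneWeights, list[BagResult]]:
    """Bagged CGUFS with AUC-weighted linear combination of gene weights.

    ``c`` defaults to the number of samples of X. With ``unweighted``
    every a_i is 1 and no labels are needed. Bags whose a_i < 0.5 are
    kept by default (the linear combination is applied literally);
    ``drop_poor_bags`` excludes them. A bag whose CGUFS run fails is
    skipped with a warning; if every bag fails, an error is raised.

    ``standardize_bags`` re-z-scores each bag's gene rows before
    fitting: the alternating optimisation assumes z-scored genes, and a
    bootstrap draw of columns no longer satisfies that.
    """
    if c is None:
        c = X.n_samples
    if labels is None and not unweighted:
        raise ValueError(
            "gene labels are required for AUC-weighted bagging; "
            "pass unweighted=True for label-free use"
        )
    ss = np.random.SeedSequence(seed)
    bag_seed, *fit_seeds = (int(s) % (2**31) for s in ss.generate_state(b + 1))
    bags = bootstrap_bags(X, b, c, seed=bag_seed)
    results: list[BagResult] = []
    draws = _reconstruct_draws(X, bags)
    for i, bag in enumerate(bags):
        try:
            if standardize_bags:
                bag = zscore_genes(bag)
            W_i, state, _ = run_cgufs(
                bag, K=K, r=r, alpha=alpha, beta=beta, seed=fit_seeds[i],
                tol=tol, max_iter=max_iter, restarts=restarts,
                linear_alpha_u=linear_alpha_u,
            )
        except Exception as exc:  # noqa: BLE001 - bag-level robustness
            warnings.warn(f"bag {i} failed and was skipped: {exc}",
                          RuntimeWarning, stacklevel=2)
            continue
        a_i = 1.0 if unweighted else bag_auc(W_i, labels)
        results.append(BagResult(i, draws[i], W_i, a_i, state))
    if not results:
        raise RuntimeError("every bag failed; no ensemble weights produced")
    kept = [
        res for res in results if not (drop_poor_bags and res.auc < 0.5)
    ] or results
    w_final = np.zeros(X.n_genes)
    for res in kept:
        w_final += res.auc * res.weights.w
    return GeneWeights(w_final, list(X.gene_ids)), results


def _reconstruct_draws(
    X: ExpressionMatrix, bags: list[ExpressionMatrix]
) -> list[np.ndarray]:
    index = {sid: i for i, sid in enumerate(X.sample_ids)}
    draws = []
    for bag in bags:
        draws.append(
            np.array([index[sid.split("#")[0]] for sid in bag.sample_ids])
        )
    return draws


def consensus_gene_set(ranked_lists: list[RankedGeneList], k: int) -> set[str]:
    """Genes in the top-k prefix of every list (the stable core set)."""
    if len(ranked_lists) < 2:
        raise ValueError("need at least two ranked lists")
    universe = set(ranked_lists[0].gene_ids)
    for lst in ranked_lists[1:]:
        if set(lst.gene_ids) != universe:
            raise ValueError("ranked lists are over different gene universes")
    core = set(ranked_lists[0].top(k))
    for lst in ranked_lists[1:]:
        core &= set(lst.top(k))
    return core
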