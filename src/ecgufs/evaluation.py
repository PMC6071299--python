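"""Evaluation of ranked gene lists against binary disease labels.

ROC and precision-recall curves are built by a threshold sweep over the
ranking restricted to labeled genes; equal weights are grouped into one
threshold step, so the trapezoidal AUC coincides with the Mann-Whitney
statistic with half credit for ties. AUPR uses step interpolation
(precision treated as a step function of recall). Also provides the
top-k coincidence machinery used to quantify stability of gene rankings
across repeated runs, and a linear-SVM cross-validation check of a
selected feature-gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .cgufs import RankedGeneList
from .preprocess import ExpressionMatrix, GeneLabelSet

logger = logging.getLogger("ecgufs")

__all__ = [
    "EvalCurves",
    "roc_pr_curves",
    "topk_overlap",
    "overlap_matrix",
    "cv_accuracy",
    "write_curves",
    "write_overlap_matrix",
]


@dataclass
class EvalCurves:
    """ROC/PR curves and their areas for one ranked list."""

    roc_points: np.ndarray  # (n+1, 2) columns FPR, TPR; starts (0,0) ends (1,1)
    pr_points: np.ndarray   # (n, 2) columns recall, precision
    auc: float
    aupr: float


def _labeled_scores(
    ranked: RankedGeneList, labels: GeneLabelSet
) -> tuple[np.ndarray, np.ndarray]:
    """Weights and binary labels of the labeled genes, in ranked order."""
    pairs = [
        (ranked.weights[i], labels[g])
        for i, g in enumerate(ranked.gene_ids)
        if g in labels
    ]
    if not pairs:
        raise ValueError("no labeled genes present in the ranked list")
    scores = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one positive and one negative labeled gene")
    return scores, y


def roc_pr_curves(ranked: RankedGeneList, labels: GeneLabelSet) -> EvalCurves:
    """Threshold sweep over the labeled genes of a ranked list.

    Genes with equal weight form a single threshold step; AUC is the
    trapezoidal area under the ROC curve and AUPR the step-interpolated
    area under the PR curve.
    """
    scores, y = _labeled_scores(ranked, labels)
    P = int(y.sum())
    N = int(y.size - P)
    # group ties: boundaries where the (already descending) score changes
    boundary = np.flatnonzero(np.diff(scores) != 0)
    ends = np.append(boundary, y.size - 1)  # inclusive end of each group
    tp = np.cumsum(y)[ends]
    fp = (ends + 1) - tp
    tpr = np.concatenate([[0.0], tp / P])
    fpr = np.concatenate([[0.0], fp / N])
    auc = float(np.trapezoid(tpr, fpr))
    recall = tp / P
    precision = tp / (tp + fp)
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    aupr = float(np.sum((recall - prev_recall) * precision))
    return EvalCurves(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        auc=auc,
        aupr=aupr,
    )


def _check_same_universe(a: RankedGeneList, b: RankedGeneList) -> None:
    if set(a.gene_ids) != set(b.gene_ids):
        raise ValueError("ranked lists are over different gene universes")


def topk_overlap(a: RankedGeneList, b: RankedGeneList, k: int) -> tuple[int, float]:
    """Coincidence of two rankings: |top-k(a) ∩ top-k(b)| and its fraction of k."""
    _check_same_universe(a, b)
    count = len(set(a.top(k)) & set(b.top(k)))
    return count, count / k


def overlap_matrix(lists: list[RankedGeneList], k: int) -> np.ndarray:
    """Pairwise top-k overlap counts; symmetric, diagonal = k."""
    m = len(lists)
    if m < 2:
        raise ValueError("need at least two ranked lists")
    out = np.full((m, m), k, dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            count, _ = topk_overlap(lists[i], lists[j], k)
            out[i, j] = out[j, i] = count
    return out


def cv_accuracy(
    X_subset: ExpressionMatrix,
    sample_labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold accuracy of a linear SVM (C = 1.0).

    Samples are the observations, the selected feature genes the
    predictors; ``sample_labels`` is the binary disease/normal status of
    each sample.
    """
    y = np.asarray(sample_labels)
    if y.size != X_subset.n_samples:
        raise ValueError("sample_labels length must match the sample count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("sample labels must be binary")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts.min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds: smallest class has {counts.min()} samples"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    clf = SVC(kernel="linear", C=1.0)
    scores = cross_val_score(clf, X_subset.values.T, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def write_curves(curves: EvalCurves, out_dir: str | Path, prefix: str = "eval") -> None:
    """Write ROC and PR points as TSV files plus a summary of the areas."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        out_dir / f"{prefix}_roc.tsv", curves.roc_points,
        delimiter="\t", header="fpr\ttpr", comments="",
    )
    np.savetxt(
        out_dir / f"{prefix}_pr.tsv", curves.pr_points,
        delimiter="\t", header="recall\tprecision", comments="",
    )
    (out_dir / f"{prefix}_summary.tsv").write_text(
        f"auc\taupr\n{curves.auc:.6f}\t{curves.aupr:.6f}\n"
    )


def write_overlap_matrix(
    counts: np.ndarray, k: int, path: str | Path, names: list[str] | None = None
) -> None:
    """Write an upper-triangular ``count(percent)`` coincidence table."""
    m = counts.shape[0]
    if names is None:
        names = [f"E{i + 1}" for i in range(m)]
    lines = ["\t" + "\t".join(names[1:])]
    for i in range(m - 1):
        cells = []
        for j in range(1, m):
            if j <= i:
                cells.append("")
            else:
                c = counts[i, j]
                cells.append(f"{c}({100.0 * c / k:.1f}%)")
        lines.append(names[i] + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
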