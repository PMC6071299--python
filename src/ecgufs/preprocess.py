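"""Loading, filtering and normalisation of gene expression matrices.

The pipeline mirrors the usual preparation for unsupervised feature
selection on bulk RNA-Seq: drop genes with any zero expression value,
rescale each sample to unit total, keep the most variable genes, then
z-score each gene so the downstream alternating optimisation is
well-conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ecgufs")

__all__ = [
    "ExpressionMatrix",
    "GeneLabelSet",
    "read_expression",
    "filter_zero_genes",
    "normalize_samples",
    "top_variance_genes",
    "zscore_genes",
    "read_gene_labels",
    "merge_gene_lists",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with aligned identifiers.

    ``values[i, j]`` is the expression level of gene ``gene_ids[i]`` in
    sample ``sample_ids[j]``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, s = self.values.shape
        if g < 1:
            raise ValueError("expression matrix needs at least one gene")
        if s < 2:
            raise ValueError("expression matrix needs at least two samples")
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {g} rows"
            )
        if len(self.sample_ids) != s:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {s} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by integer index, preserving order of ``index``."""
        index = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            self.values[index],
            [self.gene_ids[i] for i in index],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneLabelSet:
    """Binary disease-association labels for a (sub)set of genes.

    ``labels[gene_id] == 1`` marks a known disease-associated gene,
    ``0`` a known non-associated gene. The set may cover only part of an
    expression matrix; unlabeled genes are simply outside the ground
    truth.
    """

    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for gid, lab in self.labels.items():
            ilab = int(lab)
            if ilab not in (0, 1):
                raise ValueError(f"label for {gid!r} must be 0 or 1, got {lab!r}")
            clean[str(gid)] = ilab
        self.labels = clean

    @property
    def n_positive(self) -> int:
        return sum(v == 1 for v in self.labels.values())

    @property
    def n_negative(self) -> int:
        return sum(v == 0 for v in self.labels.values())

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, gid: str) -> bool:
        return gid in self.labels

    def __getitem__(self, gid: str) -> int:
        return self.labels[gid]


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix: first column gene ids, header sample ids.

    Parameters
    ----------
    path:
        TSV (default) or CSV file.
    dialect:
        ``"tsv"`` or ``"csv"``.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    # locate the first non-numeric cell, if any, for a precise error
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    mat = ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )
    logger.info(
        "read_expression: %d genes x %d samples from %s",
        mat.n_genes, mat.n_samples, path,
    )
    return mat


def filter_zero_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Delete every gene whose expression is zero in any sample."""
    keep = np.flatnonzero(np.all(X.values != 0, axis=1))
    if keep.size == 0:
        raise ValueError("filter_zero_genes removed every gene")
    out = X.subset_genes(keep)
    logger.info(
        "filter_zero_genes: kept %d / %d genes", out.n_genes, X.n_genes
    )
    return out


def normalize_samples(X: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample (column) to unit total expression."""
    if np.any(X.values < 0):
        raise ValueError("normalize_samples requires non-negative expression")
    sums = X.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"sample {X.sample_ids[zero[0]]!r} has zero total expression"
        )
    return ExpressionMatrix(X.values / sums, list(X.gene_ids), list(X.sample_ids))


def top_variance_genes(X: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest across-sample variance.

    Ties are broken by original gene order and the relative order of the
    retained genes is preserved. ``n >= n_genes`` is the identity.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= X.n_genes:
        return X
    var = X.values.var(axis=1)
    # stable sort on -var: ties keep input order
    top = np.sort(np.argsort(-var, kind="stable")[:n])
    out = X.subset_genes(top)
    logger.info("top_variance_genes: kept %d / %d genes", n, X.n_genes)
    return out


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to mean 0, unit standard deviation.

    Uses the population standard deviation (divide by the number of
    samples). Constant genes cannot be scaled and are mapped to all-zero
    rows with a warning.
    """
    if X.n_samples < 2:
        raise ValueError("z-scoring needs at least two samples")
    mean = X.values.mean(axis=1, keepdims=True)
    sd = X.values.std(axis=1, ddof=0, keepdims=True)
    constant = np.flatnonzero(sd.ravel() == 0)
    if constant.size:
        logger.warning(
            "zscore_genes: %d constant gene(s) mapped to zero rows "
            "(first: %s)", constant.size, X.gene_ids[constant[0]],
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    values = (X.values - mean) / safe_sd
    values[constant] = 0.0
    return ExpressionMatrix(values, list(X.gene_ids), list(X.sample_ids))


def read_gene_labels(path: str | Path) -> GeneLabelSet:
    """Read a two-column gene_id / {0,1} label file (TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty label file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns gene_id, label")
    # tolerate a header line
    first = df.iloc[0, 1]
    if first not in ("0", "1"):
        df = df.iloc[1:]
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no label rows")
    labels: dict[str, int] = {}
    for _, row in df.iterrows():
        gid, lab = str(row.iloc[0]), str(row.iloc[1]).strip()
        if lab not in ("0", "1"):
            raise ValueError(f"{path}: non-binary label {lab!r} for gene {gid!r}")
        labels[gid] = int(lab)
    out = GeneLabelSet(labels)
    logger.info(
        "read_gene_labels: %d genes (%d positive, %d negative) from %s",
        len(out), out.n_positive, out.n_negative, path,
    )
    return out


def merge_gene_lists(*lists: list[str]) -> list[str]:
    """Order-preserving union of gene id lists (first occurrence wins)."""
    seen: set[str] = set()
    merged: list[str] = []
    for lst in lists:
        for gid in lst:
            if gid not in seen:
                seen.add(gid)
                merged.append(gid)
    return merged
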