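"""Profile-matrix comparison: scaling, SVD imputation, PCA, correlation clustering.

The comparison stage treats a taxa-by-profiles matrix (rows = taxa, columns =
sample x primer-set profiles, plus optionally the combined profile) the way
the common web tools for omics matrices do: rows are unit-variance scaled,
missing cells are imputed by iterative low-rank SVD approximation before PCA,
and the heatmap dendrograms use correlation distance (1 - Pearson) with
average (UPGMA) linkage on centred, unit-scaled rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from skbio import TreeNode

#: admissibility threshold on the missing-value fraction per row/column
MAX_MISSING_FRACTION = 0.9999


def _check_matrix(m: pd.DataFrame) -> None:
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(f"matrix must be at least 2x2, got {m.shape}")
    row_missing = m.isna().mean(axis=1)
    col_missing = m.isna().mean(axis=0)
    if (row_missing > MAX_MISSING_FRACTION).any() or (col_missing > MAX_MISSING_FRACTION).any():
        raise ValueError("a row or column exceeds the missing-value threshold")


def preprocess(m: pd.DataFrame, scaling: str = "unit_variance") -> pd.DataFrame:
    """Row-wise scaling: ``none``, ``center``, or ``unit_variance``.

    Unit-variance scaling maps each row to mean 0, sample variance 1
    (ddof=1).  Constant rows cannot be scaled and are dropped with a warning.
    Idempotent: scaling an already-scaled matrix changes nothing.
    """
    _check_matrix(m)
    if scaling == "none":
        return m.copy()
    if scaling not in ("center", "unit_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    centered = m.sub(m.mean(axis=1), axis=0)
    if scaling == "center":
        return centered
    std = m.std(axis=1, ddof=1)
    constant = std == 0
    if constant.any():
        dropped = list(m.index[constant])
        warnings.warn(
            f"dropping {len(dropped)} constant row(s) under unit-variance scaling: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        centered = centered.loc[~constant]
        std = std.loc[~constant]
    return centered.div(std, axis=0)


def svd_impute(
    m: pd.DataFrame, rank: int = 2, tol: float = 1e-6, max_iter: int = 100
) -> pd.DataFrame:
    """Fill missing cells by iterative rank-``rank`` SVD approximation.

    Missing cells start at their row means; each iteration replaces them with
    the corresponding entries of the current best rank-k approximation until
    successive imputations move less than ``tol`` (max-abs) or ``max_iter``.
    Observed cells are never altered.
    """
    mask = m.isna().to_numpy()
    if not mask.any():
        return m.copy()
    if mask.all(axis=1).any() or mask.all(axis=0).any():
        raise ValueError("a row or column is entirely missing; cannot impute")
    X = m.to_numpy(dtype=float).copy()
    row_means = np.nanmean(X, axis=1)
    X[mask] = np.take(row_means, np.where(mask)[0])
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        k = min(rank, len(s))
        approx = (U[:, :k] * s[:k]) @ Vt[:k]
        delta = np.max(np.abs(X[mask] - approx[mask]))
        X[mask] = approx[mask]
        if delta < tol:
            break
    return pd.DataFrame(X, index=m.index, columns=m.columns)


@dataclass
class PCAResult:
    """Column profiles projected onto principal components.

    ``scores`` is profiles x components, ``loadings`` rows x components;
    ``scores @ loadings.T`` reconstructs the column-centred matrix.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray


def pca(m: pd.DataFrame) -> PCAResult:
    """PCA over the column profiles of a complete matrix (rows are features)."""
    if m.isna().any().any():
        raise ValueError("matrix has missing cells; impute first")
    X = m.to_numpy(dtype=float).T  # observations = column profiles
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=m.index, columns=comp),
        explained_pct=explained,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def correlation_distance(m: pd.DataFrame, axis: int = 1) -> np.ndarray:
    """Condensed 1 - Pearson distances between columns (axis=1) or rows (axis=0)."""
    X = m.to_numpy(dtype=float)
    if axis == 1:
        X = X.T
    return pdist(X, metric="correlation")


def hcluster(m: pd.DataFrame, axis: int = 1) -> ClusterResult:
    """Average-linkage (UPGMA) clustering under correlation distance.

    ``axis=1`` clusters columns (profiles), ``axis=0`` rows (taxa).  Distances
    are d(x, y) = 1 - Pearson(x, y) in [0, 2]; constant items are rejected
    because their correlation is undefined.
    """
    labels = list(m.columns if axis == 1 else m.index)
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    X = m.to_numpy(dtype=float)
    if axis == 1:
        X = X.T
    if np.any(X.std(axis=1) == 0):
        raise ValueError("constant profile: correlation distance undefined")
    dist = pdist(X, metric="correlation")
    Z = average(dist)
    order = [labels[i] for i in leaves_list(Z)]
    tree = TreeNode.from_linkage_matrix(Z, labels)
    newick = str(tree).strip()
    return ClusterResult(linkage=Z, labels=labels, leaf_order=order, newick=newick)
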