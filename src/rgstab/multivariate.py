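"""Exploratory multivariate views of Cq profiles.

Two ClustVis-style analyses: PCA of row-scaled profiles with SVD-based
imputation of missing values, and agglomerative hierarchical clustering
(UPGMA, correlation distance) of rows and/or columns.

Rows (features) are centered and scaled to unit variance before either
analysis; PCA scores are per sample (column), components come from the
SVD of the scaled matrix, and variance explained is proportional to the
squared singular values.  Missing cells are filled by iterative low-rank
SVD imputation (default rank 2, capped at 100 iterations, converged when
the largest fill change drops below 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

__all__ = ["PCAResult", "Dendrogram", "ClustVisPCA", "pca_clustvis", "hier_cluster"]


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    var_explained_pct: np.ndarray
    n_imputation_iters: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.scores


@dataclass
class Dendrogram:
    """A scipy-format merge table plus the induced leaf order."""

    linkage: np.ndarray         # (n-1, 4): cluster, cluster, height, size
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.linkage, columns=["cluster_a", "cluster_b", "height", "size"]
        )
        df.index.name = "merge"
        return df


def _row_scale(arr: np.ndarray, center: bool = True) -> np.ndarray:
    """Center rows and scale them to unit variance (ddof=1), NaN-aware."""
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0) or np.any(np.isnan(sd)):
        raise ValueError("zero-variance feature row(s); cannot unit-scale")
    out = (arr - mean) / sd if center else arr / sd
    return out


class ClustVisPCA(BaseEstimator):
    """PCA with row unit-variance scaling and SVD imputation.

    Fit on an ``(n_samples, n_features)`` matrix (sklearn orientation;
    features are the qPCR assays).  Missing values allowed.  Component
    signs are fixed so each loading vector's largest-magnitude entry is
    positive.

    Attributes: ``components_`` (loadings, features x k is transposed to
    sklearn's k x features), ``scores_`` (samples x k),
    ``explained_variance_ratio_``, ``n_iter_imputation_``.
    """

    def __init__(self, n_components: Optional[int] = None, impute_rank: int = 2,
                 max_iter: int = 100, tol: float = 1e-6):
        self.n_components = n_components
        self.impute_rank = impute_rank
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        arr = np.asarray(X, float).T  # features x samples internally
        nfeat, nsamp = arr.shape
        if nfeat < 2 or nsamp < 2:
            raise ValueError("PCA requires at least 2 features and 2 samples")
        if np.any(np.all(np.isnan(arr), axis=1)):
            raise ValueError("all-missing feature row")
        z = _row_scale(arr)
        miss = np.isnan(z)
        iters = 0
        if miss.any():
            filled = np.where(miss, 0.0, z)  # rows are centered; 0 = row mean
            for iters in range(1, self.max_iter + 1):
                u, s, vt = np.linalg.svd(filled, full_matrices=False)
                k = min(self.impute_rank, len(s))
                approx = (u[:, :k] * s[:k]) @ vt[:k]
                change = np.abs(filled[miss] - approx[miss]).max()
                filled[miss] = approx[miss]
                if change < self.tol:
                    break
            z = filled
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        k = self.n_components or len(s)
        k = min(k, len(s))
        # deterministic signs: largest-|loading| entry of each component > 0
        for j in range(len(s)):
            i = int(np.abs(u[:, j]).argmax())
            if u[i, j] < 0:
                u[:, j] *= -1
                vt[j] *= -1
        var = s**2
        self.singular_values_ = s[:k]
        self.components_ = u[:, :k].T
        self.scores_ = (vt[:k].T * s[:k])
        self.explained_variance_ratio_ = var / var.sum()
        self.n_iter_imputation_ = iters
        self.n_features_in_ = nfeat
        return self

    def transform(self, X):
        """Project new samples (rows) onto the fitted components."""
        arr = np.asarray(X, float).T
        return (self.components_ @ _row_scale(arr)).T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def pca_clustvis(x: pd.DataFrame, n_components: Optional[int] = None,
                 impute_rank: int = 2) -> PCAResult:
    """ClustVis-style PCA of a features x samples matrix (NaN = missing)."""
    est = ClustVisPCA(n_components=n_components, impute_rank=impute_rank)
    est.fit(x.T)
    k = est.scores_.shape[1]
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(est.scores_, index=list(x.columns), columns=comps),
        loadings=pd.DataFrame(est.components_.T, index=list(x.index), columns=comps),
        var_explained_pct=100.0 * est.explained_variance_ratio_,
        n_imputation_iters=est.n_iter_imputation_,
    )


def _upgma(profiles: np.ndarray, labels: list[str]) -> Dendrogram:
    if profiles.shape[0] < 2:
        raise ValueError("clustering requires at least 2 items")
    sds = profiles.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = [labels[i] for i in np.where(sds == 0)[0]]
        raise ValueError(f"zero-variance item(s), correlation undefined: {bad}")
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize fp noise
    link = hierarchy.average(squareform(dist, checks=False))
    return Dendrogram(link, labels)


def hier_cluster(
    x: pd.DataFrame, axis: str = "both", scale_rows: bool = True
) -> dict[str, Dendrogram]:
    """UPGMA on correlation distance for rows and/or columns.

    Rows are centered and unit-variance scaled first (the heat-map
    convention); row/column profiles are then clustered with distance
    1 − Pearson r and unweighted average linkage.  Ties keep the input
    order (scipy's deterministic agglomeration).
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError("axis must be 'rows', 'columns' or 'both'")
    arr = x.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("hier_cluster requires a complete matrix")
    scaled = _row_scale(arr) if scale_rows else arr
    out: dict[str, Dendrogram] = {}
    if axis in ("rows", "both"):
        out["rows"] = _upgma(scaled, [str(i) for i in x.index])
    if axis in ("columns", "both"):
        out["columns"] = _upgma(scaled.T, [str(c) for c in x.columns])
    return out
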