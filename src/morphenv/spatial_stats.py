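"""Spatial-coherence and group-separation statistics.

Moran's I quantifies spatial autocorrelation of a feature over soma
positions (expectation -1/(n-1) under random labeling); feature variance
summarises within-region spread as the mean standard deviation of the top
three principal components; the confusion score is the ratio of mean
within-group to mean between-group pairwise distance (lower = better
separated); the Gini coefficient summarises inequality of subregion volumes.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA


def knn_weight_matrix(positions: np.ndarray, k: int = 10) -> np.ndarray:
    """Row-normalized symmetrized binary kNN spatial weights."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    _, idx = cKDTree(positions).query(positions, k=k + 1)
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, idx[:, 1:].ravel()] = 1.0
    A = np.maximum(A, A.T)
    return A / A.sum(axis=1, keepdims=True)


def morans_index(
    positions: np.ndarray,
    values: np.ndarray,
    k_neighbors: int = 10,
    W: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Moran's I per feature column and the mean over non-constant features.

    Uses row-normalized symmetrized binary kNN weights (k = 10 by default).
    Zero-variance features are skipped with a warning; an all-constant field
    is an error.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n = values.shape[0]
    if W is None:
        W = knn_weight_matrix(positions, k_neighbors)
    s0 = W.sum()
    z = values - values.mean(axis=0)
    denom = (z * z).sum(axis=0)
    out = np.full(values.shape[1], np.nan)
    ok = denom > 0
    if not ok.any():
        raise ValueError("all features constant; Moran's I undefined")
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} zero-variance feature(s) skipped")
    num = (z[:, ok] * (W @ z[:, ok])).sum(axis=0)
    out[ok] = n / s0 * num / denom[ok]
    return out, float(np.nanmean(out))


def feature_variance(values: np.ndarray, n_components: int = 3) -> float:
    """Mean standard deviation of the top principal-component scores."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("feature_variance needs >= 2 points")
    k = min(n_components, values.shape[1], len(values))
    scores = PCA(n_components=k).fit_transform(values)
    return float(np.std(scores, axis=0, ddof=0).mean())


def confusion_score(values: np.ndarray, labels) -> float:
    """Mean intra-group / mean inter-group pairwise distance.

    Groups with fewer than two members are excluded with a warning.  A score
    near 1 means groups are indistinguishable; lower means better separated.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in np.unique(labels)]
    members = {g: np.nonzero(labels == g)[0] for g in groups}
    kept = [g for g in groups if len(members[g]) >= 2]
    if len(kept) < len(groups):
        warnings.warn(f"excluded {len(groups) - len(kept)} singleton group(s)")
    if len(kept) < 2:
        raise ValueError("confusion score needs >= 2 groups with >= 2 members")
    intra = [float(pdist(values[members[g]]).mean()) for g in kept]
    inter = [
        float(cdist(values[members[a]], values[members[b]]).mean())
        for i, a in enumerate(kept)
        for b in kept[i + 1:]
    ]
    return float(np.mean(intra) / np.mean(inter))


def gini(volumes) -> float:
    """Gini coefficient of a set of non-negative volumes via sorted cumulative shares."""
    v = np.sort(np.asarray(volumes, dtype=float))
    if v.size == 0:
        raise ValueError("empty volume list")
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("volumes must be >= 0 with positive sum")
    n = v.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ v / (n * v.sum()))


def variance_improvement(parent_values: np.ndarray, child_labels) -> float:
    """Percent change of feature variance after subdividing a region.

    Mean of the children's feature variances relative to the parent's;
    negative values mean the subdivision made the region more homogeneous.
    """
    parent_values = np.asarray(parent_values, dtype=float)
    labels = np.asarray(child_labels)
    parent_var = feature_variance(parent_values)
    if parent_var == 0:
        raise ValueError("degenerate parent variance")
    child_vars = [
        feature_variance(parent_values[labels == g])
        for g in np.unique(labels)
        if (labels == g).sum() >= 2
    ]
    if not child_vars:
        raise ValueError("no child with >= 2 members")
    return float((np.mean(child_vars) - parent_var) / parent_var * 100.0)
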