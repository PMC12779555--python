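"""24-feature neuron morphometry, QC filtering, standardization and mRMR.

Each local dendritic arbor is summarised by a fixed-order 24-dimensional
feature vector: tree-topology counts, bounding-box extents, length and volume
totals, branch-shape averages, a box-counting fractal dimension, and the
first principal axis (components and explained-variance ratios) of the node
point cloud.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .swc import NeuronSkeleton, branch_paths

FEATURE_NAMES: tuple[str, ...] = (
    "Stems",
    "Bifurcations",
    "Branches",
    "Tips",
    "OverallWidth",
    "OverallHeight",
    "OverallDepth",
    "TotalLength",
    "Volume",
    "MaxEuclideanDistance",
    "MaxPathDistance",
    "MaxBranchOrder",
    "AvgContraction",
    "AvgFragmentation",
    "AvgParentDaughterRatio",
    "AvgBifurcationAngleLocal",
    "AvgBifurcationAngleRemote",
    "HausdorffDimension",
    "PC11",
    "PC12",
    "PC13",
    "PCVarRatio1",
    "PCVarRatio2",
    "PCVarRatio3",
)

BOX_COUNT_SCALES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


class DegenerateSkeletonError(ValueError):
    """Skeleton too small for feature extraction."""


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def hausdorff_dimension(points: np.ndarray, scales=BOX_COUNT_SCALES) -> float:
    """Box-counting dimension of a 3D point set.

    Counts occupied cubic boxes at each grid scale (µm) and returns the
    least-squares slope of log N(s) against log(1/s).
    """
    points = np.asarray(points, dtype=float)
    origin = points.min(axis=0)
    counts = []
    for s in scales:
        cells = np.floor((points - origin) / s).astype(np.int64)
        counts.append(len(np.unique(cells, axis=0)))
    logn = np.log(np.asarray(counts, dtype=float))
    logi = np.log(1.0 / np.asarray(scales, dtype=float))
    slope = np.polyfit(logi, logn, 1)[0]
    return float(slope)


def extract_features(skel: NeuronSkeleton) -> pd.Series:
    """Compute the 24-dimensional morphological feature vector of one skeleton.

    The skeleton is expected to be resampled and cropped; at least two nodes
    are required.  Angle averages over a skeleton with no bifurcations are
    reported as 0 with a warning.
    """
    if skel.n_nodes < 2:
        raise DegenerateSkeletonError(f"{skel.neuron_id}: need >= 2 nodes")
    children = skel.children()
    root = skel.root
    xyz = skel.xyz
    radius = skel.radius

    n_children = np.array([len(c) for c in children])
    is_bif = (n_children >= 2) & (np.arange(skel.n_nodes) != root)
    bifs = np.nonzero(is_bif)[0]
    tips = [i for i in range(skel.n_nodes) if n_children[i] == 0 and i != root]
    paths = branch_paths(skel)

    seg_len = skel.segment_lengths()
    total_length = float(seg_len.sum())

    # path distance from root along the tree (parents precede children
    # after normalization, so a single forward pass suffices)
    path_dist = np.zeros(skel.n_nodes)
    for i in range(skel.n_nodes):
        p = skel.parent[i]
        if p >= 0:
            path_dist[i] = path_dist[p] + seg_len[i]

    # branch order: number of bifurcations on the root->node path
    order = np.zeros(skel.n_nodes, dtype=int)
    for i in range(skel.n_nodes):
        p = skel.parent[i]
        if p >= 0:
            order[i] = order[p] + (1 if is_bif[p] else 0)

    # per-branch contraction and fragmentation
    contractions, fragmentations = [], []
    for path in paths:
        plen = float(seg_len[path[1:]].sum())
        fragmentations.append(len(path) - 1)
        if plen > 0:
            contractions.append(float(np.linalg.norm(xyz[path[-1]] - xyz[path[0]]) / plen))

    # bifurcation-anchored averages
    pd_ratios, local_angles, remote_angles = [], [], []
    next_breakpoint: dict[int, int] = {}
    for path in paths:
        next_breakpoint[path[0]] = path[-1] if len(path) > 1 else path[0]
    # map (bifurcation, child) -> endpoint of that child branch
    child_end = {(p[0], p[1]): p[-1] for p in paths}
    for b in bifs:
        if radius[b] > 0:
            for c in children[b]:
                pd_ratios.append(float(radius[c] / radius[b]))
        c1, c2 = children[b][0], children[b][1]
        local_angles.append(_angle_deg(xyz[c1] - xyz[b], xyz[c2] - xyz[b]))
        e1, e2 = child_end[(b, c1)], child_end[(b, c2)]
        remote_angles.append(_angle_deg(xyz[e1] - xyz[b], xyz[e2] - xyz[b]))
    if len(bifs) == 0:
        warnings.warn(f"{skel.neuron_id}: no bifurcations; angle features set to 0")

    # conical-frustum volume per segment
    has_parent = skel.parent >= 0
    r1 = radius[skel.parent[has_parent]]
    r2 = radius[has_parent]
    volume = float(
        np.sum(np.pi / 3.0 * seg_len[has_parent] * (r1 * r1 + r1 * r2 + r2 * r2))
    )

    extent = xyz.max(axis=0) - xyz.min(axis=0)

    # principal axes of the node point cloud
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered / len(xyz)
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    evals = np.clip(evals, 0.0, None)
    pc1 = evecs[:, 0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    ratios = evals / evals.sum() if evals.sum() > 0 else np.array([1.0, 0.0, 0.0])

    values = {
        "Stems": float(n_children[root]),
        "Bifurcations": float(len(bifs)),
        "Branches": float(len(paths)),
        "Tips": float(len(tips)),
        "OverallWidth": float(extent[0]),
        "OverallHeight": float(extent[1]),
        "OverallDepth": float(extent[2]),
        "TotalLength": total_length,
        "Volume": volume,
        "MaxEuclideanDistance": float(np.linalg.norm(xyz - xyz[root], axis=1).max()),
        "MaxPathDistance": float(path_dist.max()),
        "MaxBranchOrder": float(order.max()),
        "AvgContraction": float(np.mean(contractions)) if contractions else 0.0,
        "AvgFragmentation": float(np.mean(fragmentations)) if fragmentations else 0.0,
        "AvgParentDaughterRatio": float(np.mean(pd_ratios)) if pd_ratios else 0.0,
        "AvgBifurcationAngleLocal": float(np.mean(local_angles)) if local_angles else 0.0,
        "AvgBifurcationAngleRemote": float(np.mean(remote_angles)) if remote_angles else 0.0,
        "HausdorffDimension": hausdorff_dimension(xyz),
        "PC11": float(pc1[0]),
        "PC12": float(pc1[1]),
        "PC13": float(pc1[2]),
        "PCVarRatio1": float(ratios[0]),
        "PCVarRatio2": float(ratios[1]),
        "PCVarRatio3": float(ratios[2]),
    }
    return pd.Series(values, index=list(FEATURE_NAMES), name=skel.neuron_id)


def extract_feature_table(skeletons) -> pd.DataFrame:
    """Feature vectors for an iterable of skeletons, indexed by neuron id."""
    rows = [extract_features(s) for s in skeletons]
    table = pd.DataFrame(rows)
    table.index.name = "neuron_id"
    return table


# ---------------------------------------------------------------------------
# QC, standardization, feature selection


def qc_filter(
    table: pd.DataFrame,
    reference: pd.DataFrame,
    area_of: dict | pd.Series,
    margin: float = 0.05,
    features: tuple[str, str] = ("TotalLength", "Bifurcations"),
) -> pd.Series:
    """Accept neurons whose Total Length and #Bifurcations fall within the
    reference range of their brain area, widened by ``margin`` of the range.

    ``area_of`` maps neuron id -> brain area for both tables.  Neurons in an
    area with no reference data are flagged unscored and rejected with a
    warning.
    """
    area_of = pd.Series(dict(area_of)) if not isinstance(area_of, pd.Series) else area_of
    ref_area = area_of.reindex(reference.index)
    accept = pd.Series(False, index=table.index)
    for nid in table.index:
        area = area_of.get(nid)
        ref = reference.loc[ref_area == area, list(features)]
        if len(ref) == 0:
            warnings.warn(f"{nid}: no reference neurons for area {area!r}; unscored")
            continue
        ok = True
        for f in features:
            lo, hi = float(ref[f].min()), float(ref[f].max())
            pad = margin * (hi - lo)
            v = float(table.at[nid, f])
            if v < lo - pad or v > hi + pad:
                ok = False
                break
        accept.at[nid] = ok
    return accept


def standardize(
    table: pd.DataFrame, params: tuple[pd.Series, pd.Series] | None = None
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """z-score each column (population denominator).

    Returns the standardized table and the fitted ``(mean, std)`` so that the
    same transform can be reused downstream.  Zero-variance columns map to
    zeros with a warning.  A single-row table cannot be standardized.
    """
    if params is None:
        if len(table) < 2:
            raise ValueError("standardize needs >= 2 rows")
        mean = table.mean()
        std = table.std(ddof=0)
    else:
        mean, std = params
    zero = std == 0
    if params is None and zero.any():
        warnings.warn(f"zero-variance columns set to 0: {list(table.columns[zero])}")
    safe = std.replace(0, 1.0)
    out = (table - mean) / safe
    out.loc[:, zero[zero].index] = 0.0
    return out, (mean, std)


def _discretize(col: pd.Series, bins: int = 10) -> np.ndarray:
    ranked = col.rank(method="first")
    q = pd.qcut(ranked, q=min(bins, col.nunique()), labels=False, duplicates="drop")
    return np.asarray(q)


def mrmr_top_k(
    table: pd.DataFrame, labels, k: int = 3, bins: int = 10
) -> list[str]:
    """Greedy minimal-Redundancy-Maximum-Relevance feature selection.

    Features are discretized into equal-frequency bins; relevance is mutual
    information with the labels and redundancy is the mean mutual information
    with already-selected features (difference criterion).  Ties break by
    column order, making the result deterministic.
    """
    if k > table.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {table.shape[1]}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("mRMR needs >= 2 classes")
    disc = {c: _discretize(table[c], bins) for c in table.columns}
    relevance = {c: mutual_info_score(labels, disc[c]) for c in table.columns}
    selected: list[str] = []
    remaining = list(table.columns)
    while len(selected) < k:
        best, best_score = None, -np.inf
        for c in remaining:
            if selected:
                red = np.mean([mutual_info_score(disc[c], disc[s]) for s in selected])
            else:
                red = 0.0
            score = relevance[c] - red
            if score > best_score + 1e-12:
                best, best_score = c, score
        selected.append(best)
        remaining.remove(best)
    return selected
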