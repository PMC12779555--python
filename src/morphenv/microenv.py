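"""Microenvironment construction: neighbor selection and spatially weighted
feature aggregation.

A microenvironment blends a target neuron's standardized feature vector with
up to five spatial neighbors.  Candidates are all neurons within a sphere of
radius R around the target soma; when more than five candidates exist, the
five closest in standardized feature space are kept.  Member vectors are
combined with softmax weights exp(-d_i/D) / sum_j exp(-d_j/D), where d_i is
the spatial distance to the target (d_0 = 0 for the target itself, which
therefore carries the largest weight).

The default radius R = 166.36 µm is the 75th percentile, over all neurons,
of the distance to the sixth-nearest neuron; D defaults to R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_RADIUS_UM = 166.36


@dataclass
class MicroenvConfig:
    radius: float = DEFAULT_RADIUS_UM       # candidate sphere R, µm
    decay: float | None = None              # D in the weight kernel; None -> R
    max_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.max_neighbors < 0:
            raise ValueError("max_neighbors must be >= 0")

    @property
    def D(self) -> float:
        return self.radius if self.decay is None else self.decay


@dataclass
class Microenvironment:
    target_id: object
    neighbor_ids: list
    distances: np.ndarray   # µm, target first with d_0 = 0
    weights: np.ndarray
    features: pd.Series     # aggregated standardized features


def compute_radius(somas: pd.DataFrame, kth: int = 6, percentile: float = 75.0) -> float:
    """Candidate radius: the ``percentile`` of per-neuron distances to the
    ``kth``-nearest other neuron (linear-interpolation percentile)."""
    xyz = somas[["x", "y", "z"]].to_numpy(float)
    if len(xyz) < kth + 1:
        raise ValueError(f"need >= {kth + 1} somas, got {len(xyz)}")
    d, _ = cKDTree(xyz).query(xyz, k=kth + 1)
    return float(np.percentile(d[:, kth], percentile))


def spatial_weights(distances, D: float) -> np.ndarray:
    """Softmax of -d/D over the member distances (target included, d_0 = 0)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    e = np.exp(-(d - d.min()) / D)
    return e / e.sum()


def aggregate(features: pd.DataFrame, weights) -> pd.Series:
    """Element-wise weighted sum of member feature vectors."""
    w = np.asarray(weights, dtype=float)
    if len(features) != len(w):
        raise ValueError("features and weights length mismatch")
    return pd.Series(features.to_numpy(float).T @ w, index=features.columns)


def select_neighbors(
    target_id,
    somas: pd.DataFrame,
    features_std: pd.DataFrame,
    cfg: MicroenvConfig = MicroenvConfig(),
    tree: cKDTree | None = None,
) -> tuple[list, np.ndarray]:
    """Neighbor ids and spatial distances for one target.

    All other neurons within ``cfg.radius`` are candidates; if there are more
    than ``cfg.max_neighbors``, the ones closest in standardized feature space
    win, ties broken by table order.
    """
    xyz = somas[["x", "y", "z"]].to_numpy(float)
    ids = list(somas.index)
    pos = ids.index(target_id)
    if tree is None:
        tree = cKDTree(xyz)
    cand = tree.query_ball_point(xyz[pos], cfg.radius)
    cand = [c for c in cand if c != pos]
    if len(cand) > cfg.max_neighbors:
        f = features_std.to_numpy(float)
        fdist = np.linalg.norm(f[cand] - f[pos], axis=1)
        order = np.lexsort((cand, fdist))  # feature distance, then table order
        cand = [cand[i] for i in order[: cfg.max_neighbors]]
    sdist = np.linalg.norm(xyz[cand] - xyz[pos], axis=1)
    return [ids[c] for c in cand], sdist


def build_microenvironment(
    target_id,
    somas: pd.DataFrame,
    features_std: pd.DataFrame,
    cfg: MicroenvConfig = MicroenvConfig(),
    tree: cKDTree | None = None,
) -> Microenvironment:
    nbr_ids, nbr_dist = select_neighbors(target_id, somas, features_std, cfg, tree)
    member_ids = [target_id] + nbr_ids
    d = np.concatenate([[0.0], nbr_dist])
    w = spatial_weights(d, cfg.D)
    agg = aggregate(features_std.loc[member_ids], w)
    agg.name = target_id
    return Microenvironment(target_id, nbr_ids, d, w, agg)


def build_all(
    somas: pd.DataFrame,
    features_std: pd.DataFrame,
    cfg: MicroenvConfig = MicroenvConfig(),
) -> pd.DataFrame:
    """Microenvironment feature table for every neuron, in input order.

    Mirrors the single-neuron feature table schema, plus ``n_neighbors`` and
    ``mean_neighbor_distance`` columns.
    """
    features_std = features_std.loc[somas.index]
    tree = cKDTree(somas[["x", "y", "z"]].to_numpy(float))
    rows, n_nbrs, mean_d = [], [], []
    for nid in somas.index:
        me = build_microenvironment(nid, somas, features_std, cfg, tree)
        rows.append(me.features)
        n_nbrs.append(len(me.neighbor_ids))
        mean_d.append(float(me.distances[1:].mean()) if len(me.neighbor_ids) else 0.0)
    out = pd.DataFrame(rows, index=somas.index)
    out["n_neighbors"] = n_nbrs
    out["mean_neighbor_distance"] = mean_d
    out.index.name = "neuron_id"
    return out
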