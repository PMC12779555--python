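"""Data-driven subparcellation of atlas regions from microenvironment features.

For each eligible region (>= 40 neurons, >= 225 µm extent on every axis) a
graph of "connected neurons" is built: an edge joins two neurons when either
is among the other's top-N spatial neighbors, weighted by exp(-feature
distance).  Leiden community detection plus a 5-nearest-neighbor majority
vote yields per-neuron community labels; the (N, shape-scaling) combination
is chosen adaptively by silhouette score in standardized microenvironment
feature space.  Labels are voxelized by nearest-neighbor interpolation,
smoothed with two rounds of ball-kernel median filtering (radius 5 voxels),
and components smaller than 512 voxels are dissolved into their most
face-adjacent neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from sklearn.metrics import silhouette_score

from .atlas import AtlasVolume, VOXEL_SIZE_UM


@dataclass
class ParcellationConfig:
    candidate_N: tuple[int, ...] = (50, 100, 250, 500)
    scaling_options: tuple[bool, ...] = (False, True)
    leiden_resolution: float = 0.5
    random_seed: int = 0
    min_neurons: int = 40
    min_extent_um: float = 225.0
    vote_k: int = 5
    median_radius_voxels: int = 5
    median_rounds: int = 2
    min_subregion_voxels: int = 512
    # silhouette floor below which a region is left unparcellated; calibrated
    # on the null model of the synthetic generator (see docs/methods.md)
    min_silhouette: float = 0.10
    voxel_size: float = VOXEL_SIZE_UM


@dataclass
class ShapeScaling:
    """Per-axis scaling derived from the PCA of a region's edge voxels.

    ``A`` holds the square roots of the PCA eigenvalues; ``factors[i] =
    sum(A) / A[i]``, so the shortest region axis is stretched the most and
    ``sum(1/factors) = 1``.
    """

    A: np.ndarray          # (3,) square-rooted eigenvalues, µm
    factors: np.ndarray    # (3,)
    rotation: np.ndarray   # (3, 3) columns = principal axes
    center: np.ndarray     # (3,) µm

    def transform(self, xyz_um: np.ndarray) -> np.ndarray:
        return ((np.atleast_2d(xyz_um) - self.center) @ self.rotation) * self.factors


@dataclass
class Parcellation:
    region_id: int
    neuron_labels: pd.Series          # refined community label per neuron
    voxel_labels: np.ndarray          # full-frame int array, subregion ids 1..K
    subregions: pd.DataFrame          # local_id, voxels, volume_mm3
    chosen_N: int
    chosen_scaling: bool
    silhouette: float


# ---------------------------------------------------------------------------
# eligibility and shape scaling


def eligibility(mask: np.ndarray, n_neurons: int, cfg: ParcellationConfig = ParcellationConfig()) -> bool:
    """A region qualifies with >= ``min_neurons`` neurons and every
    bounding-box extent >= ``min_extent_um``."""
    if not mask.any():
        return False
    if n_neurons < cfg.min_neurons:
        return False
    idx = np.nonzero(mask)
    extents = [(i.max() - i.min() + 1) * cfg.voxel_size for i in idx]
    return all(e >= cfg.min_extent_um for e in extents)


def edge_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask 6-neighbor (volume border counts)."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(mask, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return mask & ~interior


def shape_scaling(mask: np.ndarray, voxel_size: float = VOXEL_SIZE_UM) -> ShapeScaling:
    """PCA of the region's edge-voxel coordinates → per-axis scaling factors."""
    ev = np.argwhere(edge_voxels(mask))
    if len(ev) < 4:
        raise ValueError("need >= 4 edge voxels for shape scaling")
    pts = (ev + 0.5) * voxel_size
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    A = np.sqrt(np.clip(evals, 0.0, None))
    A = np.maximum(A, voxel_size)  # floor degenerate (planar) axes
    factors = A.sum() / A
    return ShapeScaling(A=A, factors=factors, rotation=evecs, center=center)


# ---------------------------------------------------------------------------
# graph, communities, refinement


def build_graph(
    positions: np.ndarray, features: np.ndarray, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Edges and weights of the connected-neuron graph.

    Edge (i, j) exists when i is among j's top-N spatial neighbors or vice
    versa (union rule); weight = exp(-||F_i - F_j||).
    """
    positions = np.asarray(positions, dtype=float)
    features = np.asarray(features, dtype=float)
    n = len(positions)
    if N >= n:
        raise ValueError(f"N={N} must be < n={n}")
    _, idx = cKDTree(positions).query(positions, k=N + 1)
    pairs = set()
    for i in range(n):
        for j in idx[i, 1:]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int)
    fdist = np.linalg.norm(features[edges[:, 0]] - features[edges[:, 1]], axis=1)
    return edges, np.exp(-fdist)


def detect_communities(
    edges: np.ndarray,
    weights: np.ndarray,
    n: int,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition (modularity objective with resolution) of the graph."""
    if n == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(map(float, weights)),
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


def majority_vote(labels: np.ndarray, positions: np.ndarray, k: int = 5) -> np.ndarray:
    """One synchronous pass of modal relabeling among the k spatially nearest
    neurons (self excluded); ties keep the current label."""
    labels = np.asarray(labels)
    n = len(labels)
    if n <= k:
        return labels.copy()
    _, idx = cKDTree(positions).query(positions, k=k + 1)
    out = labels.copy()
    for i in range(n):
        nbr = labels[idx[i, 1:]]
        vals, counts = np.unique(nbr, return_counts=True)
        winners = vals[counts == counts.max()]
        if len(winners) == 1:
            out[i] = winners[0]
        # ties (multiple modal labels) keep the current label
    return out


def _cluster_chain(
    positions: np.ndarray,
    features_std: np.ndarray,
    N: int,
    scaling: ShapeScaling | None,
    cfg: ParcellationConfig,
) -> np.ndarray:
    pos = scaling.transform(positions) if scaling is not None else positions
    edges, weights = build_graph(pos, features_std, N)
    labels = detect_communities(
        edges, weights, len(positions), cfg.leiden_resolution, cfg.random_seed
    )
    return majority_vote(labels, pos, cfg.vote_k)


def select_parameters(
    positions: np.ndarray,
    features_std: np.ndarray,
    mask: np.ndarray,
    cfg: ParcellationConfig = ParcellationConfig(),
) -> tuple[int, bool, float, np.ndarray] | None:
    """Adaptive parameterization: best (N, scaling) by silhouette score.

    Every candidate N (< neuron count) is combined with scaling on/off; the
    graph→Leiden→vote chain is run for each, and the mean silhouette of the
    labels in standardized microenvironment feature space picks the winner
    (ties: smaller N, scaling off).  A configuration only counts when every
    community holds at least ``cfg.min_neurons`` members — the same support
    floor that gates region eligibility; splinter communities smaller than
    that cannot form a credible subregion yet grossly inflate silhouette.
    Returns ``None`` when no configuration yields >= 2 valid communities.
    """
    n = len(positions)
    candidates = [N for N in cfg.candidate_N if N < n]
    if not candidates:
        return None
    scal = shape_scaling(mask, cfg.voxel_size) if True in cfg.scaling_options else None
    best: tuple[int, bool, float, np.ndarray] | None = None
    for N in sorted(candidates):
        for use_scaling in sorted(cfg.scaling_options):  # False before True
            labels = _cluster_chain(
                positions, features_std, N, scal if use_scaling else None, cfg
            )
            _, counts = np.unique(labels, return_counts=True)
            if len(counts) < 2 or counts.min() < cfg.min_neurons:
                continue
            score = float(silhouette_score(features_std, labels))
            if best is None or score > best[2] + 1e-12:
                best = (N, bool(use_scaling), score, labels)
    return best


# ---------------------------------------------------------------------------
# voxel operations


def voxelize(
    mask: np.ndarray,
    soma_xyz: np.ndarray,
    labels: np.ndarray,
    voxel_size: float = VOXEL_SIZE_UM,
) -> np.ndarray:
    """Nearest-neighbor interpolation of neuron community labels onto the
    region mask (voxel centers vs soma positions, µm).  Background stays 0;
    community labels are written as label+1 to keep 0 free."""
    if len(soma_xyz) == 0:
        raise ValueError("no labeled neurons")
    out = np.zeros(mask.shape, dtype=np.int32)
    vox = np.argwhere(mask)
    centers = (vox + 0.5) * voxel_size
    _, nearest = cKDTree(np.asarray(soma_xyz, float)).query(centers)
    out[tuple(vox.T)] = np.asarray(labels)[nearest] + 1
    return out


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2 <= r * r).astype(float)


def smooth(
    volume: np.ndarray,
    radius_voxels: int = 5,
    rounds: int = 2,
) -> np.ndarray:
    """Median filtering of a label volume restricted to its foreground.

    Background (0) voxels are excluded from every neighborhood median and are
    never modified, so the mask is conserved exactly.  The median is the
    lower median, which resolves even-count ties to the smallest label id.
    """
    out = volume.copy()
    kernel = _ball(radius_voxels)
    mask = out > 0
    for _ in range(rounds):
        labels_present = np.unique(out[mask])
        counts = np.stack(
            [
                np.round(fftconvolve((out == lab).astype(float), kernel, mode="same"))
                for lab in labels_present
            ]
        )
        total = counts.sum(axis=0)
        target_rank = np.floor((total + 1) / 2.0)  # lower-median rank
        cum = np.cumsum(counts, axis=0)
        choice = np.argmax(cum >= target_rank[None], axis=0)
        new = labels_present[choice]
        out = np.where(mask, new, 0).astype(volume.dtype)
    return out


def _label_components(volume: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """26-connected components per label value; returns a component-id volume
    (-1 background) and a list of (component_id -> label value, size)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    comp = np.full(volume.shape, -1, dtype=np.int32)
    info: list[tuple[int, int]] = []
    next_id = 0
    for lab in np.unique(volume[volume > 0]):
        cc, ncc = ndimage.label(volume == lab, structure=structure)
        for c in range(1, ncc + 1):
            sel = cc == c
            comp[sel] = next_id
            info.append((int(lab), int(sel.sum())))
            next_id += 1
    return comp, info


def _face_adjacency(comp: np.ndarray) -> dict[tuple[int, int], int]:
    """Counts of shared voxel faces between distinct components."""
    counts: dict[tuple[int, int], int] = {}
    for axis in range(3):
        a = np.take(comp, range(comp.shape[axis] - 1), axis=axis)
        b = np.take(comp, range(1, comp.shape[axis]), axis=axis)
        sel = (a >= 0) & (b >= 0) & (a != b)
        pairs = np.stack([np.minimum(a[sel], b[sel]), np.maximum(a[sel], b[sel])])
        if pairs.size:
            uniq, cnt = np.unique(pairs.T, axis=0, return_counts=True)
            for (i, j), c in zip(uniq, cnt):
                counts[(int(i), int(j))] = counts.get((int(i), int(j)), 0) + int(c)
    return counts


def prune_small(
    volume: np.ndarray,
    min_voxels: int = 512,
    parent_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dissolve sub-minimum connected components and renumber subregions.

    Labels are split into 26-connected components; every component smaller
    than ``min_voxels`` is merged into the adjacent component sharing the
    most voxel faces (iterated smallest-first).  Components of the same
    community label that sit on different islands of a disconnected parent
    mask keep a single subregion id.  If the whole region holds fewer than
    ``min_voxels`` voxels it is returned unchanged as one subregion.
    """
    mask = volume > 0
    total = int(mask.sum())
    out = volume.copy()
    if total < min_voxels:
        final = np.where(mask, 1, 0).astype(np.int32)
        table = pd.DataFrame(
            {"local_id": [1], "voxels": [total],
             "volume_mm3": [total * (VOXEL_SIZE_UM / 1000.0) ** 3]}
        )
        return final, table

    frozen = np.zeros(volume.shape, dtype=bool)  # isolated islands kept as-is
    while True:
        comp, info = _label_components(out)
        sizes = np.array([s for _, s in info])
        candidates = [
            c for c in range(len(info))
            if sizes[c] < min_voxels and not frozen[comp == c].any()
        ]
        if len(info) <= 1 or not candidates:
            break
        small = min(candidates, key=lambda c: sizes[c])
        adj = _face_adjacency(comp)
        neighbors: dict[int, int] = {}
        for (i, j), c in adj.items():
            if i == small:
                neighbors[j] = neighbors.get(j, 0) + c
            elif j == small:
                neighbors[i] = neighbors.get(i, 0) + c
        sel = comp == small
        if not neighbors:
            # island with no in-mask neighbor: nothing to dissolve into
            frozen[sel] = True
            continue
        target = max(sorted(neighbors), key=lambda t: neighbors[t])
        out[sel] = info[target][0]

    # final subregion numbering: same community label on different parent
    # islands shares one id; multiple components within one island are
    # distinct subregions
    comp, info = _label_components(out)
    if parent_mask is None:
        parent_mask = mask
    islands, _ = ndimage.label(parent_mask, structure=np.ones((3, 3, 3), dtype=bool))
    final = np.zeros(out.shape, dtype=np.int32)
    key_to_id: dict[tuple[int, int], int] = {}
    # rank components of each label within their island by size (desc)
    per_island_label: dict[tuple[int, int], int] = {}
    order = np.argsort([-s for _, s in info])
    rows = []
    for cid in order:
        lab = info[cid][0]
        sel = comp == cid
        island = int(np.bincount(islands[sel]).argmax())
        rank = per_island_label.get((island, lab), 0)
        per_island_label[(island, lab)] = rank + 1
        key = (lab, rank)
        if key not in key_to_id:
            key_to_id[key] = len(key_to_id) + 1
        final[sel] = key_to_id[key]
    for local_id in sorted(set(key_to_id.values())):
        nvox = int((final == local_id).sum())
        rows.append(
            {"local_id": local_id, "voxels": nvox,
             "volume_mm3": nvox * (VOXEL_SIZE_UM / 1000.0) ** 3}
        )
    return final, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# region-level driver and atlas assembly


def parcellate_region(
    region_id: int,
    mask: np.ndarray,
    somas: pd.DataFrame,
    me_features_std: pd.DataFrame,
    cfg: ParcellationConfig = ParcellationConfig(),
) -> Parcellation | None:
    """Full subparcellation of one region; ``None`` if ineligible, if no
    configuration yields structure, or if the best silhouette falls below the
    documented floor."""
    in_region = somas["region_id"] == region_id
    somas = somas.loc[in_region]
    if not eligibility(mask, len(somas), cfg):
        return None
    positions = somas[["x", "y", "z"]].to_numpy(float)
    feats = me_features_std.loc[somas.index].to_numpy(float)
    picked = select_parameters(positions, feats, mask, cfg)
    if picked is None:
        return None
    N, use_scaling, score, labels = picked
    if score < cfg.min_silhouette:
        return None
    vol = voxelize(mask, positions, labels, cfg.voxel_size)
    vol = smooth(vol, cfg.median_radius_voxels, cfg.median_rounds)
    final, table = prune_small(vol, cfg.min_subregion_voxels, parent_mask=mask)
    if table["local_id"].nunique() < 2:
        return None
    return Parcellation(
        region_id=region_id,
        neuron_labels=pd.Series(labels, index=somas.index, name="community"),
        voxel_labels=final,
        subregions=table,
        chosen_N=N,
        chosen_scaling=use_scaling,
        silhouette=score,
    )


def assemble_atlas(
    base: AtlasVolume, parcellations: list[Parcellation]
) -> tuple[AtlasVolume, pd.DataFrame, dict]:
    """Rewrite subdivided regions with fresh subregion ids and extend the
    ontology (children ``<acronym>-R<k>`` under each parent)."""
    labels = base.labels.astype(np.int64).copy()
    ontology = base.ontology.copy()
    next_id = int(ontology["id"].max()) + 1
    rows, sub_rows = [], []
    seen = set()
    for parc in parcellations:
        if parc.region_id in seen:
            raise ValueError(f"duplicate parcellation for region {parc.region_id}")
        seen.add(parc.region_id)
        parent = ontology.loc[ontology["id"] == parc.region_id].iloc[0]
        region_mask = base.labels == parc.region_id
        for _, sub in parc.subregions.iterrows():
            new_id = next_id
            next_id += 1
            sel = region_mask & (parc.voxel_labels == sub["local_id"])
            labels[sel] = new_id
            rows.append(
                {"id": new_id, "acronym": f"{parent['acronym']}-R{int(sub['local_id'])}",
                 "parent_id": int(parc.region_id), "area": parent["area"]}
            )
            sub_rows.append(
                {"new_id": new_id, "parent_id": int(parc.region_id),
                 "name": f"{parent['acronym']}-R{int(sub['local_id'])}",
                 "voxels": int(sub["voxels"]), "volume_mm3": float(sub["volume_mm3"])}
            )
    ontology = pd.concat([ontology, pd.DataFrame(rows)], ignore_index=True)
    out = AtlasVolume(labels=labels.astype(np.uint32), ontology=ontology,
                      voxel_size=base.voxel_size)
    n_subdivided = len(parcellations)
    summary = {
        "regions_before": int(base.ontology.shape[0]),
        "regions_after": int(base.ontology.shape[0]) + len(sub_rows),
        "subparcellated": n_subdivided,
        "mean_subregions": float(np.mean([len(p.subregions) for p in parcellations]))
        if parcellations else 0.0,
    }
    return out, pd.DataFrame(sub_rows), summary
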