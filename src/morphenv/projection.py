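"""Axonal projection vectors over atlas labels and projection-specificity
summaries.

An axon resampled to 2-µm node spacing contributes ~2 µm of cable per node,
so per-region axonal length is the node count in that region times the
spacing.  Projection intensity is ln(length + 1) with length in millimetres;
for clustering contexts, regions receiving less than 1 mm of axon are
excluded.  Hemisphere side (ipsi/contra) is taken relative to the soma
against the atlas mid-z plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasVolume
from .swc import AXON, NeuronSkeleton, resample

SPACING_UM = 2.0
MIN_LENGTH_MM = 1.0


def extract_axon(skel: NeuronSkeleton, spacing: float = SPACING_UM) -> NeuronSkeleton:
    """Type-2 (axon) nodes of a resampled morphology.

    Axon subtrees are detached from their non-axon parents; an axonless
    neuron yields an empty skeleton.
    """
    rs = resample(skel, spacing)
    keep = np.nonzero(rs.types == AXON)[0]
    index = {old: i for i, old in enumerate(keep)}
    parent = np.array(
        [
            index.get(int(rs.parent[old]), -1) if rs.parent[old] >= 0 else -1
            for old in keep
        ]
    )
    return NeuronSkeleton(
        neuron_id=rs.neuron_id,
        ids=np.arange(1, len(keep) + 1),
        types=rs.types[keep],
        xyz=rs.xyz[keep],
        radius=rs.radius[keep],
        parent=parent,
        header=rs.header,
    )


def region_lengths(
    axon: NeuronSkeleton,
    atlas: AtlasVolume,
    soma_xyz: np.ndarray,
    spacing: float = SPACING_UM,
) -> dict[tuple[object, str], float]:
    """Axonal length (µm) binned by (region label, ipsi/contra) plus an
    ``("unassigned", "na")`` bucket for out-of-atlas nodes.

    Length per node = resampling spacing; the map conserves total length:
    sum of all entries = spacing × node count.
    """
    out: dict[tuple[object, str], float] = {}
    if axon.n_nodes == 0:
        return out
    labels = atlas.label_at(axon.xyz)
    soma_side = atlas.hemisphere_of(np.atleast_2d(soma_xyz))[0]
    sides = atlas.hemisphere_of(axon.xyz)
    for lab, side in zip(labels, sides):
        if lab == 0:
            key = ("unassigned", "na")
        else:
            key = (int(lab), "ipsi" if side == soma_side else "contra")
        out[key] = out.get(key, 0.0) + spacing
    return out


def projection_vector(
    lengths_mm: pd.Series | dict,
    min_length_mm: float = MIN_LENGTH_MM,
    exclude_below_min: bool = False,
) -> pd.Series:
    """Intensity = ln(length + 1) with length in mm.

    With ``exclude_below_min`` (the clustering convention) entries shorter
    than ``min_length_mm`` are zeroed.
    """
    s = pd.Series(lengths_mm, dtype=float)
    if (s < 0).any():
        raise ValueError("negative axonal length")
    out = np.log(s + 1.0)
    if exclude_below_min:
        out[s < min_length_mm] = 0.0
    return out


def projection_matrix(
    axons: dict[object, NeuronSkeleton],
    atlas: AtlasVolume,
    somas: pd.DataFrame,
    spacing: float = SPACING_UM,
    exclude_below_min: bool = False,
) -> pd.DataFrame:
    """Projection-intensity matrix: rows = neurons, columns = ``<region>_<side>``."""
    rows = {}
    for nid, axon in axons.items():
        soma = somas.loc[nid, ["x", "y", "z"]].to_numpy(float)
        lengths = region_lengths(axon, atlas, soma, spacing)
        mm = {
            f"{k[0]}_{k[1]}": v / 1000.0
            for k, v in lengths.items()
            if k[0] != "unassigned"
        }
        rows[nid] = projection_vector(mm, exclude_below_min=exclude_below_min)
    mat = pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)
    mat.index.name = "neuron_id"
    return mat


@dataclass
class SpecificityReport:
    spatial_std: pd.DataFrame        # per parent region: parent vs mean subregion std
    correlations: pd.DataFrame       # pairwise Pearson r between subregion profiles
    target_counts: pd.DataFrame      # per subregion: targets above threshold


def _axon_spatial_std(axons: list[NeuronSkeleton]) -> float:
    pts = np.vstack([a.xyz for a in axons if a.n_nodes > 0])
    return float(np.std(pts, axis=0, ddof=0).mean())


def specificity_report(
    axons: dict[object, NeuronSkeleton],
    proj: pd.DataFrame,
    region_of: pd.Series,
    subregion_of: pd.Series,
    min_neurons: int = 5,
    min_length_mm: float = MIN_LENGTH_MM,
) -> SpecificityReport:
    """Projection specificity of subregions relative to their parent regions.

    Only groups with at least ``min_neurons`` neurons enter, matching the
    study's reporting rule.  For each parent region: (i) the spatial standard
    deviation of pooled axonal node coordinates versus the mean over its
    subregions; (ii) Pearson correlations between subregion-mean projection
    vectors; (iii) per-subregion counts of targets receiving at least
    ``exp(ln(min_length_mm + 1)) - 1`` mm of axon.
    """
    region_of = pd.Series(region_of)
    subregion_of = pd.Series(subregion_of)
    std_rows, corr_rows, count_rows = [], [], []
    thresh = float(np.log(min_length_mm + 1.0))
    for region in sorted(region_of.unique()):
        nids = region_of.index[region_of == region]
        nids = [n for n in nids if n in axons]
        if len(nids) < min_neurons:
            warnings.warn(f"region {region}: fewer than {min_neurons} neurons, skipped")
            continue
        parent_std = _axon_spatial_std([axons[n] for n in nids])
        sub_stds, sub_means = [], {}
        for sub in sorted(subregion_of.loc[nids].unique()):
            sub_nids = [n for n in nids if subregion_of[n] == sub]
            if len(sub_nids) < min_neurons:
                continue
            sub_stds.append(_axon_spatial_std([axons[n] for n in sub_nids]))
            sub_means[sub] = proj.loc[sub_nids].mean(axis=0)
            count_rows.append(
                {"region": region, "subregion": sub,
                 "n_targets": int((sub_means[sub] >= thresh).sum())}
            )
        if sub_stds:
            std_rows.append(
                {"region": region, "parent_std": parent_std,
                 "mean_subregion_std": float(np.mean(sub_stds)),
                 "n_subregions": len(sub_stds)}
            )
        subs = sorted(sub_means)
        for i, a in enumerate(subs):
            for b in subs[i + 1:]:
                va, vb = sub_means[a].to_numpy(), sub_means[b].to_numpy()
                if va.std() == 0 or vb.std() == 0:
                    continue
                corr_rows.append(
                    {"region": region, "sub_a": a, "sub_b": b,
                     "pearson_r": float(np.corrcoef(va, vb)[0, 1])}
                )
    return SpecificityReport(
        spatial_std=pd.DataFrame(std_rows),
        correlations=pd.DataFrame(corr_rows),
        target_counts=pd.DataFrame(count_rows),
    )
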