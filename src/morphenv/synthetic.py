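"""Seeded generators for synthetic atlases, zoned neuron populations and
zone-specific axons.

The generators emulate the statistical structure the analysis assumes: somas
scattered inside labeled regions, planted subregion "zones" with
zone-specific dendritic geometry (total length, branch length, tortuosity)
and per-zone axonal target preferences.  ``effect_size`` scales every
inter-zone parameter difference; 0 is the null model (all zones share
parameters).

Default demo scale: 100³ voxels at 25 µm, 3 regions, 3 zones per region,
300 neurons per region, seed 1024.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasVolume, VOXEL_SIZE_UM
from .swc import AXON, BASAL_DENDRITE, SOMA, NeuronSkeleton

DEFAULT_SEED = 1024
STEP_UM = 2.0


@dataclass
class ZoneSpec:
    """Morphology and projection parameters of one planted zone."""

    zone_id: int
    stems: int = 3
    branch_prob: float = 0.35            # chance to bifurcate at a branch end
    mean_branch_length: float = 40.0     # µm
    tortuosity: float = 0.8              # (0, 1]; 1 = perfectly straight growth
    total_length: float = 500.0          # µm budget per neuron
    length_cv: float = 0.1               # neuron-to-neuron budget variation
    targets: tuple[tuple[int, str, float], ...] = ()  # (region, side, mean mm)

    def __post_init__(self) -> None:
        if not (0 < self.tortuosity <= 1):
            raise ValueError("tortuosity must be in (0, 1]")
        if min(self.stems, self.mean_branch_length, self.total_length) <= 0:
            raise ValueError("zone parameters must be positive")


@dataclass
class GroundTruth:
    zone_of_neuron: pd.Series            # neuron_id -> zone label
    zone_voxels: dict                    # region_id -> full-frame int zone grid
    seed: int
    zones: dict                          # region_id -> list[ZoneSpec]


# fixed, roughly orthogonal zone directions in (total length, branch length,
# tortuosity, stems, branch probability) parameter space: zones differ like
# distinct cell types rather than along a single size axis
_ZONE_DIRECTIONS = np.array(
    [
        [0, +1, +1, 0, -1],
        [+1, -1, 0, +1, 0],
        [-1, 0, -1, +1, +1],
        [+1, +1, -1, -1, 0],
        [-1, -1, +1, 0, +1],
    ],
    dtype=float,
)


def default_zone_specs(G: int, effect_size: float = 1.0) -> list[ZoneSpec]:
    """G zone parameter sets whose pairwise differences scale with
    ``effect_size`` (0 = identical parameters, the null model)."""
    if G > len(_ZONE_DIRECTIONS):
        raise ValueError(f"at most {len(_ZONE_DIRECTIONS)} planted zones supported")
    specs = []
    for z in range(G):
        d = _ZONE_DIRECTIONS[z] * effect_size if G > 1 else np.zeros(5)
        specs.append(
            ZoneSpec(
                zone_id=z,
                total_length=500.0 * (1.0 + 0.30 * d[0]),
                mean_branch_length=40.0 * (1.0 + 0.25 * d[1]),
                tortuosity=float(np.clip(0.75 + 0.12 * d[2], 0.05, 1.0)),
                stems=int(np.clip(round(3 + 1.5 * d[3]), 1, 8)),
                branch_prob=float(np.clip(0.35 * (1.0 + 0.5 * d[4]), 0.05, 0.9)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# atlas


def make_atlas(
    n_regions: int = 3,
    shape: tuple[int, int, int] = (100, 100, 100),
    seed: int = DEFAULT_SEED,
    symmetric: bool = False,
    voxel_size: float = VOXEL_SIZE_UM,
) -> AtlasVolume:
    """Random ellipsoidal regions in a background-0 grid.

    With ``symmetric``, regions are built in the left hemisphere and mirrored
    across the mid-z plane; the mirror twin of region ``i`` is labeled
    ``i + n_regions``, so the volume equals its z-flip after relabeling.
    Overlaps resolve by priority (lower region id wins).
    """
    if min(shape) < 40:
        raise ValueError("shape must be at least 40 voxels per axis")
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.uint32)
    zmax = shape[2] // 2 if symmetric else shape[2]
    grid = np.mgrid[0: shape[0], 0: shape[1], 0:zmax].astype(float)
    axis_len = (shape[0], shape[1], zmax)
    for rid in range(1, n_regions + 1):
        lo = 4.5  # >= 9-voxel extent
        radii = np.array(
            [rng.uniform(lo, max(lo + 1.0, min((L - 3) / 2.2, L / 4))) for L in axis_len]
        )
        center = np.array(
            [rng.uniform(r + 1, s - r - 1) for r, s in zip(radii, axis_len)]
        )
        inside = (
            ((grid[0] - center[0]) / radii[0]) ** 2
            + ((grid[1] - center[1]) / radii[1]) ** 2
            + ((grid[2] - center[2]) / radii[2]) ** 2
        ) <= 1.0
        free = labels[:, :, :zmax] == 0
        labels[:, :, :zmax][inside & free] = rid
    rows = [
        {"id": rid, "acronym": f"R{rid}", "parent_id": 0, "area": "SYN"}
        for rid in range(1, n_regions + 1)
    ]
    if symmetric:
        left = labels[:, :, :zmax]
        mirrored = left[:, :, ::-1].copy()
        twin = mirrored.copy()
        twin[mirrored > 0] += n_regions
        labels[:, :, shape[2] - zmax:] = twin
        rows += [
            {"id": rid + n_regions, "acronym": f"R{rid}'", "parent_id": 0, "area": "SYN"}
            for rid in range(1, n_regions + 1)
        ]
    ontology = pd.DataFrame(rows)
    return AtlasVolume(labels=labels, ontology=ontology, voxel_size=voxel_size)


def plant_zones(
    mask: np.ndarray,
    G: int,
    layout: str = "axial",
    seed: int = DEFAULT_SEED,
    min_zone_voxels: int = 512,
) -> np.ndarray:
    """Partition a region mask into G connected zones (labels 1..G; 0 outside).

    ``axial``: quantile slabs along the mask's longest principal axis;
    ``laminar``: depth bands of the boundary distance transform;
    ``blobs``: nearest-seed assignment from G spaced random voxels.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    vox = np.argwhere(mask)
    if len(vox) < G * min_zone_voxels:
        raise ValueError(
            f"region too small for {G} zones of >= {min_zone_voxels} voxels"
        )
    rng = np.random.default_rng(seed)
    out = np.zeros(mask.shape, dtype=np.int32)
    if G == 1:
        out[mask] = 1
        return out
    if layout == "axial":
        centered = vox - vox.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        edges = np.quantile(proj, np.linspace(0, 1, G + 1)[1:-1])
        zone = np.searchsorted(edges, proj, side="right") + 1
    elif layout == "laminar":
        from scipy import ndimage

        depth = ndimage.distance_transform_edt(mask)[tuple(vox.T)]
        edges = np.quantile(depth, np.linspace(0, 1, G + 1)[1:-1])
        zone = np.searchsorted(edges, depth, side="right") + 1
    elif layout == "blobs":
        seeds = vox[rng.choice(len(vox), size=G, replace=False)]
        d = np.linalg.norm(vox[:, None, :] - seeds[None, :, :], axis=2)
        zone = d.argmin(axis=1) + 1
    else:
        raise ValueError(f"unknown layout {layout!r}")
    out[tuple(vox.T)] = zone
    counts = np.bincount(zone, minlength=G + 1)[1:]
    if counts.min() < min_zone_voxels:
        raise ValueError(
            f"zone sizes {counts.tolist()} below the {min_zone_voxels}-voxel floor"
        )
    return out


# ---------------------------------------------------------------------------
# neuron growth


def _perturb(direction: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    d = direction + sigma * rng.normal(size=3)
    n = np.linalg.norm(d)
    return d / n if n > 0 else direction


def grow_neuron(
    zone: ZoneSpec,
    soma_xyz: np.ndarray,
    seed: int,
    neuron_id: str = "synthetic",
    node_type: int = BASAL_DENDRITE,
) -> NeuronSkeleton:
    """Grow a stochastic branching dendritic tree from one soma.

    Active tips advance in ~2-µm steps with per-step direction noise scaled
    by ``1 - tortuosity`` (tortuosity 1 grows perfectly straight, so every
    branch has contraction 1).  At sampled branch-length boundaries a tip
    bifurcates with probability ``branch_prob``; growth stops when the total
    length budget is spent, so expected total length tracks the budget.
    """
    if zone.total_length <= 0:
        raise ValueError("zero growth budget: soma-only neuron")
    rng = np.random.default_rng(seed)
    sigma = 0.9 * (1.0 - zone.tortuosity)
    soma_xyz = np.asarray(soma_xyz, dtype=float)

    xyz = [soma_xyz]
    types = [SOMA]
    radius = [5.0]
    parent = [-1]

    budget = zone.total_length * float(
        np.clip(rng.normal(1.0, zone.length_cv), 0.3, None)
    )

    def sample_branch_len() -> float:
        return float(rng.exponential(zone.mean_branch_length)) + STEP_UM

    # tips: (node index, direction, remaining branch length)
    tips = []
    for _ in range(zone.stems):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        tips.append([0, d, sample_branch_len()])

    spent = 0.0
    t = 0
    while spent < budget and tips:
        tip = tips[t % len(tips)]
        d = _perturb(tip[1], sigma, rng)
        new_xyz = xyz[tip[0]] + d * STEP_UM
        xyz.append(new_xyz)
        types.append(node_type)
        radius.append(0.5)
        parent.append(tip[0])
        node = len(xyz) - 1
        spent += STEP_UM
        tip[0], tip[1], tip[2] = node, d, tip[2] - STEP_UM
        if tip[2] <= 0:
            tip[2] = sample_branch_len()
            if rng.random() < zone.branch_prob:
                d2 = _perturb(d, max(sigma, 0.4), rng)
                tips.append([node, d2, sample_branch_len()])
        t += 1
    return NeuronSkeleton(
        neuron_id=neuron_id,
        ids=np.arange(1, len(xyz) + 1),
        types=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
        header=[f"# synthetic neuron, seed {seed}"],
    )


# ---------------------------------------------------------------------------
# populations


def sample_population(
    atlas: AtlasVolume,
    n_per_region: int = 300,
    G: int = 3,
    effect_size: float = 1.0,
    seed: int = DEFAULT_SEED,
    layout: str = "axial",
    region_ids: list[int] | None = None,
    grow: bool = True,
    brain_id: str = "synthetic-brain",
) -> tuple[pd.DataFrame, dict, GroundTruth]:
    """Somas, grown skeletons and ground truth for every requested region.

    Somas are uniform within the region; each neuron follows its voxel's
    zone parameters.  ``effect_size`` 0 makes all zones share parameters
    (null model).  With ``grow=False`` only somas and ground truth are
    produced (no skeletons), for stages that synthesise features directly.
    """
    rng = np.random.default_rng(seed)
    if region_ids is None:
        region_ids = [int(r) for r in atlas.ontology["id"] if r != 0]
    soma_rows = []
    skeletons: dict[str, NeuronSkeleton] = {}
    zone_labels = {}
    zone_voxels = {}
    zone_specs_by_region = {}
    for rid in region_ids:
        mask = atlas.region_mask(rid)
        zones = plant_zones(mask, G, layout=layout, seed=int(rng.integers(2**31)))
        specs = default_zone_specs(G, effect_size)
        zone_voxels[rid] = zones
        zone_specs_by_region[rid] = specs
        vox = np.argwhere(mask)
        pick = rng.choice(len(vox), size=n_per_region, replace=True)
        offsets = rng.uniform(0, 1, size=(n_per_region, 3))
        xyz = (vox[pick] + offsets) * atlas.voxel_size
        zl = zones[tuple(vox[pick].T)]
        for j in range(n_per_region):
            nid = f"r{rid}n{j:04d}"
            spec = specs[int(zl[j]) - 1]
            soma_rows.append(
                {
                    "neuron_id": nid,
                    "x": xyz[j, 0], "y": xyz[j, 1], "z": xyz[j, 2],
                    "region_id": rid,
                    "brain_id": brain_id,
                    "hemisphere": str(atlas.hemisphere_of(xyz[j])[0]),
                }
            )
            zone_labels[nid] = int(zl[j])
            if grow:
                skeletons[nid] = grow_neuron(
                    spec, xyz[j], seed=int(rng.integers(2**31)), neuron_id=nid
                )
    somas = pd.DataFrame(soma_rows).set_index("neuron_id")
    gt = GroundTruth(
        zone_of_neuron=pd.Series(zone_labels, name="zone"),
        zone_voxels=zone_voxels,
        seed=seed,
        zones=zone_specs_by_region,
    )
    return somas, skeletons, gt


# ---------------------------------------------------------------------------
# axons


def make_axons(
    skeletons: dict,
    somas: pd.DataFrame,
    gt: GroundTruth,
    atlas: AtlasVolume,
    seed: int = DEFAULT_SEED,
    length_cv: float = 0.1,
) -> dict:
    """Append type-2 axonal arbors reaching each zone's projection targets.

    Per target, a 2-µm polyline runs from the soma to the target region and
    then meanders inside it until the in-region cable reaches the sampled
    length (mean from the zone spec, in mm).  Unreachable targets fall back
    to a straight path toward the requested centroid (logged as a warning).
    """
    rng = np.random.default_rng(seed)
    out = {}
    centroids: dict[tuple[int, str], np.ndarray] = {}

    def centroid(region: int, side_flag: str, soma_side: str) -> np.ndarray | None:
        want_right = (side_flag == "ipsi") == (soma_side == "right")
        key = (region, "right" if want_right else "left")
        if key not in centroids:
            vox = np.argwhere(atlas.labels == region)
            if len(vox):
                z_um = (vox[:, 2] + 0.5) * atlas.voxel_size
                sel = z_um >= atlas.midline_um if key[1] == "right" else z_um < atlas.midline_um
                chosen = vox[sel] if sel.any() else vox
                centroids[key] = (chosen.mean(axis=0) + 0.5) * atlas.voxel_size
            else:
                centroids[key] = None
        return centroids[key]

    for nid, skel in skeletons.items():
        zone = gt.zone_of_neuron[nid]
        rid = int(somas.at[nid, "region_id"])
        spec = gt.zones[rid][zone - 1]
        soma_side = str(somas.at[nid, "hemisphere"])
        xyz = list(skel.xyz)
        types = list(skel.types)
        radius = list(skel.radius)
        parent = list(skel.parent)
        root = skel.root
        for region, side_flag, mean_mm in spec.targets:
            c = centroid(int(region), side_flag, soma_side)
            if c is None:
                warnings.warn(f"{nid}: target region {region} not in atlas; skipped")
                continue
            budget_um = 1000.0 * mean_mm * float(
                np.clip(rng.normal(1.0, length_cv), 0.2, None)
            )
            pos = skel.xyz[root].copy()
            prev = root
            # en-route segment: straight toward the target centroid
            direction = c - pos
            dist = np.linalg.norm(direction)
            n_steps = max(int(dist / STEP_UM), 1)
            step_vec = direction / n_steps
            in_region = 0.0
            for _ in range(n_steps):
                pos = pos + step_vec
                xyz.append(pos.copy())
                types.append(AXON)
                radius.append(0.3)
                parent.append(prev)
                prev = len(xyz) - 1
            # meander inside the target until the in-region budget is spent
            d = step_vec / np.linalg.norm(step_vec)
            guard = 0
            while in_region < budget_um and guard < 100000:
                guard += 1
                d = _perturb(d, 0.6, rng)
                cand = pos + d * STEP_UM
                if atlas.label_at(cand)[0] != region:
                    d = (c - pos) / (np.linalg.norm(c - pos) + 1e-9)
                    cand = pos + d * STEP_UM
                pos = cand
                xyz.append(pos.copy())
                types.append(AXON)
                radius.append(0.3)
                parent.append(prev)
                prev = len(xyz) - 1
                if atlas.label_at(pos)[0] == region:
                    in_region += STEP_UM
        out[nid] = NeuronSkeleton(
            neuron_id=nid,
            ids=np.arange(1, len(xyz) + 1),
            types=np.array(types),
            xyz=np.array(xyz),
            radius=np.array(radius),
            parent=np.array(parent),
            header=skel.header,
        )
    return out
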