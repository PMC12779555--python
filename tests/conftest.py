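"""Shared fixtures: hand-built skeletons, synthetic atlas volumes, and the
zone-recovery pipeline helper used by parcellation-level tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphenv import microenv, morphometry, parcellation, swc, synthetic
from morphenv.atlas import AtlasVolume


def build_skeleton(rows, neuron_id="fixture"):
    """Rows of (id, type, x, y, z, radius, parent) -> normalized skeleton."""
    return swc.from_rows([tuple(r) for r in rows], neuron_id)


@pytest.fixture
def chain3():
    """Straight 3-node neurite: soma at origin, tips along +x."""
    return build_skeleton(
        [(1, 1, 0, 0, 0, 5, -1), (2, 3, 2, 0, 0, 1, 1), (3, 3, 4, 0, 0, 1, 2)],
        "chain3",
    )


@pytest.fixture
def y_tree():
    """Symmetric Y: soma below a bifurcation with two straight 5-µm daughters.

    Child segments (±3, 4, 0) meet at cos θ = 7/25, i.e. 73.7398°.
    """
    return build_skeleton(
        [
            (1, 1, 0, -2, 0, 1, -1),
            (2, 3, 0, 0, 0, 1, 1),
            (3, 3, 3, 4, 0, 1, 2),
            (4, 3, -3, 4, 0, 1, 2),
        ],
        "y_tree",
    )


def ellipsoid_atlas(shape, radii, region_id=1):
    """Single ellipsoidal region centred in the grid."""
    g = np.mgrid[0: shape[0], 0: shape[1], 0: shape[2]].astype(float)
    c = np.array(shape) / 2
    inside = (
        ((g[0] - c[0]) / radii[0]) ** 2
        + ((g[1] - c[1]) / radii[1]) ** 2
        + ((g[2] - c[2]) / radii[2]) ** 2
    ) <= 1
    labels = np.zeros(shape, np.uint32)
    labels[inside] = region_id
    ontology = pd.DataFrame(
        [{"id": region_id, "acronym": f"R{region_id}", "parent_id": 0, "area": "SYN"}]
    )
    return AtlasVolume(labels=labels, ontology=ontology)


def run_zone_recovery(G, n, shape, radii, effect_size, seed, cfg=None):
    """simulate -> features -> microenvironments -> parcellate on one region.

    Returns (n_subregions, voxel ARI vs planted zones, silhouette); the first
    two are None when the region comes back unparcellated.
    """
    from sklearn.metrics import adjusted_rand_score

    atlas = ellipsoid_atlas(shape, radii)
    mask = atlas.region_mask(1)
    somas, skels, gt = synthetic.sample_population(
        atlas, n_per_region=n, G=G, effect_size=effect_size, seed=seed, region_ids=[1]
    )
    feats = morphometry.extract_feature_table(skels.values())
    feats_std, _ = morphometry.standardize(feats)
    R = microenv.compute_radius(somas)
    me = morphometry.standardize(
        microenv.build_all(somas, feats_std, microenv.MicroenvConfig(radius=R))[
            feats.columns
        ]
    )[0]
    cfg = cfg or parcellation.ParcellationConfig(random_seed=3)
    parc = parcellation.parcellate_region(1, mask, somas, me, cfg)
    if parc is None:
        return None, None, None
    ari = adjusted_rand_score(gt.zone_voxels[1][mask], parc.voxel_labels[mask])
    return len(parc.subregions), float(ari), parc.silhouette
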