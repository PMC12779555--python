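"""Parcellation building blocks: eligibility, shape scaling, the
connected-neuron graph, Leiden, refinement, voxel post-processing, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from morphenv import parcellation
from morphenv.parcellation import ParcellationConfig
from conftest import ellipsoid_atlas


def ball_mask(shape=(30, 30, 30), radius=10):
    g = np.mgrid[0: shape[0], 0: shape[1], 0: shape[2]].astype(float)
    c = np.array(shape) / 2
    return ((g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2) <= radius**2


class TestEligibility:
    def test_too_few_neurons(self):
        assert not parcellation.eligibility(ball_mask(), 39)

    def test_boundary_accepted(self):
        # ball radius 10 voxels -> extent 21 voxels = 525 µm on each axis
        assert parcellation.eligibility(ball_mask(), 40)

    def test_thin_region_rejected(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[5:35, 5:35, 10:14] = True  # 4 voxels = 100 µm < 225 µm
        assert not parcellation.eligibility(mask, 60)


class TestShapeScaling:
    def test_ball_factors_near_three(self):
        s = parcellation.shape_scaling(ball_mask(radius=12))
        np.testing.assert_allclose(s.factors, 3.0, rtol=0.1)

    def test_slab_largest_factor_on_short_axis(self):
        mask = np.zeros((50, 20, 20), bool)
        mask[5:45, 5:15, 5:15] = True
        s = parcellation.shape_scaling(mask)
        # direct eigen-oracle: long axis has the largest sqrt-eigenvalue,
        # hence the smallest factor
        assert s.factors[0] == s.factors.min()
        assert np.sum(1.0 / s.factors) == pytest.approx(1.0, abs=1e-9)

    def test_factors_scale_invariant(self):
        small = ball_mask((30, 30, 30), 8)
        big = ndimage.binary_dilation(small, iterations=3)
        a = parcellation.shape_scaling(small).factors
        b = parcellation.shape_scaling(big).factors
        np.testing.assert_allclose(a, b, rtol=0.1)


class TestBuildGraph:
    def test_complete_graph_at_max_N(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, size=(12, 3))
        edges, w = parcellation.build_graph(pos, rng.normal(size=(12, 4)), N=11)
        assert len(edges) == 12 * 11 // 2

    def test_collinear_union_rule(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0.0]])
        edges, _ = parcellation.build_graph(pos, np.zeros((3, 2)), N=1)
        assert {tuple(e) for e in edges} == {(0, 1), (1, 2)}

    def test_identical_features_unit_weights(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 50, size=(10, 3))
        _, w = parcellation.build_graph(pos, np.zeros((10, 5)), N=3)
        np.testing.assert_allclose(w, 1.0)

    def test_matches_brute_force_knn(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 200, size=(40, 3))
        feats = rng.normal(size=(40, 6))
        N = 6
        edges, w = parcellation.build_graph(pos, feats, N)
        d = np.linalg.norm(pos[:, None] - pos[None], axis=2)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(40):
            for j in np.argsort(d[i])[:N]:
                expected.add((min(i, j), max(i, j)))
        assert {tuple(e) for e in edges} == expected
        np.testing.assert_allclose(
            w, np.exp(-np.linalg.norm(feats[edges[:, 0]] - feats[edges[:, 1]], axis=1))
        )

    def test_N_too_large(self):
        with pytest.raises(ValueError):
            parcellation.build_graph(np.zeros((5, 3)), np.zeros((5, 2)), N=5)


class TestDetectCommunities:
    def test_two_cliques(self):
        # two 6-cliques joined by a single edge
        edges, weights = [], []
        for block, off in ((0, 0), (1, 6)):
            for i in range(6):
                for j in range(i + 1, 6):
                    edges.append((off + i, off + j))
                    weights.append(1.0)
        edges.append((0, 6))
        weights.append(0.01)
        labels = parcellation.detect_communities(
            np.array(edges), np.array(weights), 12, seed=0
        )
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, size=(60, 3))
        feats = rng.normal(size=(60, 4))
        edges, w = parcellation.build_graph(pos, feats, N=8)
        a = parcellation.detect_communities(edges, w, 60, seed=42)
        b = parcellation.detect_communities(edges, w, 60, seed=42)
        assert (a == b).all()


class TestMajorityVote:
    def test_unanimous_unchanged(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 100, size=(20, 3))
        labels = np.zeros(20, dtype=int)
        assert (parcellation.majority_vote(labels, pos) == 0).all()

    def test_outlier_flipped(self):
        pos = np.array([[i, 0, 0.0] for i in range(10)])
        labels = np.zeros(10, dtype=int)
        labels[4] = 7
        out = parcellation.majority_vote(labels, pos)
        assert out[4] == 0

    def test_tie_keeps_current(self):
        # neighbor labels 2-2-1 around a target currently labeled 0
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1.0]]
        )
        labels = np.array([0, 1, 1, 2, 2, 0])
        out = parcellation.majority_vote(labels, pos, k=5)
        assert out[0] == 0


class TestVoxelOps:
    def test_voxelize_single_neuron(self):
        mask = ball_mask()
        vol = parcellation.voxelize(mask, np.array([[375.0, 375, 375]]), np.array([0]))
        assert (vol[mask] == 1).all()
        assert (vol[~mask] == 0).all()

    def test_voxelize_bisection_matches_distance_oracle(self):
        mask = np.zeros((40, 20, 20), bool)
        mask[2:38, 4:16, 4:16] = True
        somas = np.array([[5 * 25.0, 250, 250], [35 * 25.0, 250, 250]])
        vol = parcellation.voxelize(mask, somas, np.array([0, 1]))
        vox = np.argwhere(mask)
        centers = (vox + 0.5) * 25.0
        d = np.linalg.norm(centers[:, None] - somas[None], axis=2)
        np.testing.assert_array_equal(vol[tuple(vox.T)], d.argmin(axis=1) + 1)

    def test_smooth_uniform_unchanged(self):
        vol = np.where(ball_mask(), 3, 0).astype(np.int32)
        np.testing.assert_array_equal(parcellation.smooth(vol), vol)

    def test_smooth_absorbs_speckle_and_conserves_mask(self):
        mask = ball_mask()
        vol = np.where(mask, 1, 0).astype(np.int32)
        vol[15, 15, 15] = 2  # single-voxel speckle
        out = parcellation.smooth(vol)
        assert out[15, 15, 15] == 1
        np.testing.assert_array_equal(out > 0, mask)

    def test_prune_absorbs_small_island(self):
        mask = ball_mask((40, 40, 40), 14)
        vol = np.where(mask, 1, 0).astype(np.int32)
        sub = ball_mask((40, 40, 40), 4)  # ~250 voxels, under the 512 floor
        vol[sub & mask] = 2
        out, table = parcellation.prune_small(vol)
        assert table["local_id"].nunique() == 1
        assert (out[mask] > 0).all()

    def test_prune_keeps_512_component(self):
        vol = np.zeros((30, 30, 30), np.int32)
        vol[2:22, 2:22, 2:10] = 1
        vol[2:10, 2:10, 10:18] = 2  # 8*8*8 = 512 voxels exactly
        out, table = parcellation.prune_small(vol)
        assert table["local_id"].nunique() == 2
        assert int(table["voxels"].min()) == 512

    def test_prune_partitions_mask(self):
        rng = np.random.default_rng(5)
        mask = ball_mask((36, 36, 36), 13)
        somas = (np.argwhere(mask)[rng.choice(mask.sum(), 30)] + 0.5) * 25.0
        labels = rng.integers(0, 3, 30)
        vol = parcellation.voxelize(mask, somas, labels)
        out, table = parcellation.prune_small(parcellation.smooth(vol))
        np.testing.assert_array_equal(out > 0, mask)
        assert int(table["voxels"].sum()) == int(mask.sum())

    def test_tiny_region_returned_whole(self):
        vol = np.zeros((10, 10, 10), np.int32)
        vol[2:6, 2:6, 2:6] = 1  # 64 voxels < 512
        out, table = parcellation.prune_small(vol)
        assert table["local_id"].nunique() == 1
        assert int(table["voxels"].iloc[0]) == 64


class TestAssembleAtlas:
    def test_zero_parcellations_identity(self):
        atlas = ellipsoid_atlas((40, 40, 40), (12, 10, 10))
        out, table, summary = parcellation.assemble_atlas(atlas, [])
        np.testing.assert_array_equal(out.labels, atlas.labels)
        assert summary["subparcellated"] == 0 and table.empty

    def test_split_adds_regions_and_refines(self):
        atlas = ellipsoid_atlas((40, 40, 40), (14, 11, 11))
        mask = atlas.region_mask(1)
        # carve three axial slabs as a synthetic parcellation result
        vox = np.argwhere(mask)
        thirds = np.quantile(vox[:, 0], [1 / 3, 2 / 3])
        local = np.zeros(atlas.labels.shape, np.int32)
        local[tuple(vox.T)] = np.searchsorted(thirds, vox[:, 0]) + 1
        parc = parcellation.Parcellation(
            region_id=1,
            neuron_labels=pd.Series(dtype=int),
            voxel_labels=local,
            subregions=pd.DataFrame(
                {"local_id": [1, 2, 3],
                 "voxels": [int((local == k).sum()) for k in (1, 2, 3)],
                 "volume_mm3": [0.0, 0.0, 0.0]}
            ),
            chosen_N=50, chosen_scaling=False, silhouette=0.5,
        )
        out, table, summary = parcellation.assemble_atlas(atlas, [parc])
        assert len(out.ontology) == len(atlas.ontology) + 3
        # refinement: every new label maps back to exactly one parent label
        new_ids = table["new_id"].to_numpy()
        for nid in new_ids:
            assert set(np.unique(atlas.labels[out.labels == nid])) == {1}
        # region voxel totals conserved
        assert sum((out.labels == nid).sum() for nid in new_ids) == mask.sum()


class TestSelectParameters:
    def test_planted_two_zone_recovery(self):
        from conftest import run_zone_recovery

        n_sub, ari, sil = run_zone_recovery(
            G=2, n=400, shape=(64, 64, 64), radii=(28, 21, 21),
            effect_size=2.5, seed=77,
        )
        assert n_sub == 2
        assert ari >= 0.8

    def test_single_cluster_data_unparcellated(self):
        rng = np.random.default_rng(6)
        mask = ball_mask((40, 40, 40), 14)
        pos = rng.uniform(200, 800, size=(120, 3))
        feats = rng.normal(size=(120, 24))  # no spatial structure at all
        picked = parcellation.select_parameters(
            pos, feats, mask, ParcellationConfig(random_seed=1)
        )
        assert picked is None or picked[2] < 0.10
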