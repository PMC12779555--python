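"""Feature extraction against hand-computed oracles, QC, z-scoring, mRMR."""

import numpy as np
import pandas as pd
import pytest

from morphenv import morphometry, swc
from morphenv.morphometry import FEATURE_NAMES, extract_features
from conftest import build_skeleton


class TestExtractFeatures:
    def test_vector_length_and_order(self, y_tree):
        f = extract_features(y_tree)
        assert list(f.index) == list(FEATURE_NAMES)
        assert len(f) == 24
        assert np.isfinite(f.to_numpy()).all()

    def test_single_neurite(self, chain3):
        f = extract_features(chain3)
        assert f.Stems == 1
        assert f.Bifurcations == 0
        assert f.Branches == 1
        assert f.Tips == 1
        assert f.AvgContraction == pytest.approx(1.0)
        assert f.PCVarRatio1 == pytest.approx(1.0)
        assert f.TotalLength == pytest.approx(4.0)

    def test_y_tree_hand_oracle(self, y_tree):
        f = extract_features(y_tree)
        assert f.Stems == 1
        assert f.Bifurcations == 1
        assert f.Branches == 3
        assert f.Tips == 2
        # daughters (±3,4,0): cos θ = (-9+16)/25
        expected = np.degrees(np.arccos(7 / 25))
        assert f.AvgBifurcationAngleLocal == pytest.approx(expected, abs=1e-9)
        assert f.AvgBifurcationAngleRemote == pytest.approx(expected, abs=1e-9)
        assert f.TotalLength == pytest.approx(2 + 5 + 5)
        assert f.MaxPathDistance == pytest.approx(7.0)
        assert f.MaxEuclideanDistance == pytest.approx(np.sqrt(9 + 36))
        assert f.MaxBranchOrder == 1
        assert f.AvgContraction == pytest.approx(1.0)
        assert f.AvgFragmentation == pytest.approx(1.0)
        assert f.AvgParentDaughterRatio == pytest.approx(1.0)
        assert f.OverallWidth == pytest.approx(6.0)
        assert f.OverallHeight == pytest.approx(6.0)
        assert f.OverallDepth == pytest.approx(0.0)

    def test_volume_frustum(self):
        # one 3-µm segment with radii 2 -> 1: V = π/3 h (r1² + r1 r2 + r2²)
        skel = build_skeleton([(1, 1, 0, 0, 0, 2, -1), (2, 3, 3, 0, 0, 1, 1)])
        f = extract_features(skel)
        assert f.Volume == pytest.approx(np.pi / 3 * 3 * (4 + 2 + 1))

    def test_degenerate_raises(self):
        soma_only = build_skeleton([(1, 1, 0, 0, 0, 1, -1)])
        with pytest.raises(morphometry.DegenerateSkeletonError):
            extract_features(soma_only)

    def test_scale_equivariance(self, y_tree):
        f = extract_features(y_tree)
        scaled = swc.NeuronSkeleton(
            "scaled", y_tree.ids, y_tree.types, y_tree.xyz * 3.0,
            y_tree.radius, y_tree.parent,
        )
        g = extract_features(scaled)
        for name in ("TotalLength", "MaxEuclideanDistance", "MaxPathDistance",
                     "OverallWidth", "OverallHeight"):
            assert g[name] == pytest.approx(3.0 * f[name])
        for name in ("AvgContraction", "AvgBifurcationAngleLocal",
                     "PCVarRatio1", "PCVarRatio2", "PCVarRatio3"):
            assert g[name] == pytest.approx(f[name], abs=1e-9)

    def test_rotation_invariance(self, y_tree):
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        rotated = swc.NeuronSkeleton(
            "rot", y_tree.ids, y_tree.types, y_tree.xyz @ R.T,
            y_tree.radius, y_tree.parent,
        )
        f, g = extract_features(y_tree), extract_features(rotated)
        skip = {"PC11", "PC12", "PC13", "OverallWidth", "OverallHeight", "OverallDepth"}
        for name in FEATURE_NAMES:
            if name in skip:
                continue
            assert g[name] == pytest.approx(f[name], rel=1e-6, abs=1e-7), name

    def test_pc_invariants(self, y_tree):
        f = extract_features(y_tree)
        pc = np.array([f.PC11, f.PC12, f.PC13])
        assert np.linalg.norm(pc) == pytest.approx(1.0)
        ratios = [f.PCVarRatio1, f.PCVarRatio2, f.PCVarRatio3]
        assert ratios == sorted(ratios, reverse=True)
        assert sum(ratios) == pytest.approx(1.0)

    def test_hausdorff_dimension_of_line(self):
        # a dense straight line has box-counting dimension ~1
        pts = np.column_stack([np.linspace(0, 200, 400), np.zeros(400), np.zeros(400)])
        assert morphometry.hausdorff_dimension(pts) == pytest.approx(1.0, abs=0.15)


class TestQCFilter:
    def _tables(self):
        ref = pd.DataFrame(
            {"TotalLength": [100.0, 200.0], "Bifurcations": [5.0, 10.0]},
            index=["a", "b"],
        )
        area = {"a": "CTX", "b": "CTX", "q1": "CTX", "q2": "CTX", "q3": "CTX"}
        return ref, area

    def test_boundary_inside(self):
        ref, area = self._tables()
        q = pd.DataFrame({"TotalLength": [100.0], "Bifurcations": [5.0]}, index=["q1"])
        assert morphometry.qc_filter(q, ref, area).loc["q1"]

    def test_below_margin_rejected(self):
        ref, area = self._tables()
        # 5% of range [100, 200] is 5: anything under 95 fails
        q = pd.DataFrame({"TotalLength": [94.0], "Bifurcations": [7.0]}, index=["q2"])
        assert not morphometry.qc_filter(q, ref, area).loc["q2"]

    def test_degenerate_range_exact_only(self):
        ref = pd.DataFrame(
            {"TotalLength": [150.0, 150.0], "Bifurcations": [5.0, 5.0]},
            index=["a", "b"],
        )
        area = {"a": "CTX", "b": "CTX", "q1": "CTX", "q2": "CTX"}
        q = pd.DataFrame(
            {"TotalLength": [150.0, 150.1], "Bifurcations": [5.0, 5.0]},
            index=["q1", "q2"],
        )
        mask = morphometry.qc_filter(q, ref, area)
        assert mask.loc["q1"] and not mask.loc["q2"]

    def test_unscored_area_rejected_with_warning(self):
        ref, area = self._tables()
        area["q3"] = "HPF"
        q = pd.DataFrame({"TotalLength": [150.0], "Bifurcations": [7.0]}, index=["q3"])
        with pytest.warns(UserWarning, match="unscored"):
            assert not morphometry.qc_filter(q, ref, area).loc["q3"]


class TestStandardize:
    def test_population_convention(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out, _ = morphometry.standardize(t)
        np.testing.assert_allclose(out["f"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(20, 4)))
        once, _ = morphometry.standardize(t)
        twice, _ = morphometry.standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_zeroed(self):
        t = pd.DataFrame({"f": [1.0, 2.0], "c": [7.0, 7.0]})
        with pytest.warns(UserWarning):
            out, _ = morphometry.standardize(t)
        assert (out["c"] == 0).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            morphometry.standardize(pd.DataFrame({"f": [1.0]}))

    def test_params_reusable(self):
        t = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        _, params = morphometry.standardize(t)
        out, _ = morphometry.standardize(pd.DataFrame({"f": [2.0]}), params=params)
        assert out["f"].iloc[0] == pytest.approx(0.0)


class TestMRMR:
    def _data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        f1 = labels + rng.normal(0, 0.05, n)
        f2 = f1 + rng.normal(0, 1e-4, n)          # near-copy of f1
        flip = rng.random(n) < 0.3
        f3 = np.where(flip, 1 - labels, labels) + rng.normal(0, 0.05, n)
        f4 = rng.normal(size=n)                    # pure noise
        table = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3, "f4": f4})
        return table, labels

    def test_k1_is_max_relevance(self):
        table, labels = self._data()
        assert morphometry.mrmr_top_k(table, labels, k=1) == ["f1"]

    def test_redundant_copy_not_selected(self):
        table, labels = self._data()
        top2 = morphometry.mrmr_top_k(table, labels, k=2)
        assert set(top2) == {"f1", "f3"}

    def test_column_permutation_invariant_set(self):
        table, labels = self._data()
        permuted = table[["f3", "f1", "f4", "f2"]]
        assert set(morphometry.mrmr_top_k(permuted, labels, k=2)) == {"f1", "f3"}

    def test_k_too_large(self):
        table, labels = self._data(n=50)
        with pytest.raises(ValueError):
            morphometry.mrmr_top_k(table, labels, k=5)
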