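"""GLCM, run-length and NGTDM features: hand-derived cases, invariants and
brute-force oracle equivalence on tiny ROIs."""
import numpy as np
import pytest

import oracles
from conftest import full_mask, volume_from
from featuniq.core import FeatuniqError, RoiMask
from featuniq.features.glcm import Glcm, compute_glcm, glcm_features
from featuniq.features.glrlm import run_length_features, run_length_matrix
from featuniq.features.ngtdm import COARSENESS_CAP, nid_features
from featuniq.features.quantize import quantize
from featuniq.features.registry import DIRECTIONS_2D, DIRECTIONS_3D


def quantized(arr, n_levels):
    vol = volume_from(arr)
    return quantize(vol, full_mask(vol), n_levels)


class TestQuantize:
    def test_constant_roi_all_level_one(self):
        q = quantized(np.full((2, 3), 50.0), 8)
        assert np.all(q.levels == 1)

    def test_equal_width_binning_two_levels(self):
        q = quantized(np.array([[0.0, 10.0, 20.0, 30.0]]), 2)
        assert q.levels.tolist() == [1, 1, 2, 2]

    def test_bijective_when_levels_match_distinct_values(self):
        q = quantized(np.array([[0.0, 1.0, 2.0, 3.0]]), 4)
        assert q.levels.tolist() == [1, 2, 3, 4]

    def test_empty_mask_rejected(self):
        vol = volume_from(np.zeros((2, 2)))
        with pytest.raises(FeatuniqError):
            quantize(vol, RoiMask(np.zeros(vol.shape, dtype=bool)), 4)


class TestGlcm:
    def two_by_two(self, symmetric):
        q = quantized(np.array([[0.0, 0.0], [0.0, 1.0]]), 2)
        return compute_glcm(q, (0, 0, 1), 1, symmetric)

    def test_symmetric_two_by_two_probabilities(self):
        m = self.two_by_two(True)
        np.testing.assert_allclose(m.matrix, [[0.5, 0.25], [0.25, 0.0]])

    def test_asymmetric_two_by_two_probabilities(self):
        m = self.two_by_two(False)
        np.testing.assert_allclose(m.matrix, [[0.5, 0.5], [0.0, 0.0]])

    def test_constant_roi_all_mass_at_one_one(self):
        q = quantized(np.full((3, 3), 7.0), 4)
        m = compute_glcm(q, (0, 0, 1), 1, True)
        assert m.matrix[0, 0] == 1.0
        f = glcm_features(m)
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["InverseDiffNorm"] == 1.0
        assert f["InverseDiffMomentNorm"] == 1.0
        assert f["MaxProbability"] == 1.0

    def test_hand_summed_features_on_two_by_two(self):
        f = glcm_features(self.two_by_two(True))
        assert f["Energy"] == pytest.approx(0.375)
        assert f["Entropy"] == pytest.approx(1.5)
        assert f["InverseDiffNorm"] == pytest.approx(0.5 + 0.5 / 1.5, abs=1e-4)
        assert f["InverseDiffMomentNorm"] == pytest.approx(0.9)

    def test_zero_pairs_yields_undefined_features(self):
        q = quantized(np.array([[1.0]]), 2)  # single voxel: no pairs anywhere
        m = compute_glcm(q, (0, 0, 1), 1, True)
        assert m.empty
        assert all(np.isnan(v) for v in glcm_features(m).values())

    def test_mass_conservation_and_symmetry(self, rng):
        arr = rng.integers(0, 400, size=(4, 6, 6)).astype(float)
        vol = volume_from(arr)
        q = quantize(vol, full_mask(vol), 8)
        for d in DIRECTIONS_3D:
            m = compute_glcm(q, d, 1, True)
            assert m.matrix.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(m.matrix, m.matrix.T)

    def test_idn_idmn_dominate_unnormalized_homogeneities(self, rng):
        """Termwise the N_g-normalized denominators are smaller."""
        arr = rng.normal(0, 50, size=(3, 8, 8))
        vol = volume_from(arr)
        q = quantize(vol, full_mask(vol), 16)
        for d in DIRECTIONS_2D:
            f = glcm_features(compute_glcm(q, d, 1, True))
            assert f["InverseDiffNorm"] >= f["InverseDiff"]
            assert f["InverseDiffMomentNorm"] >= f["InverseDiffMoment"]

    def test_oracle_equivalence_small_rois(self, rng):
        """Every feature on random <=5x5x3 ROIs matches brute-force enumeration."""
        for trial in range(3):
            arr = rng.integers(0, 300, size=(3, 5, 5)).astype(float)
            vol = volume_from(arr)
            mask = RoiMask(rng.random(vol.shape) > 0.2)
            if mask.voxel_count < 4:
                continue
            q = quantize(vol, mask, 5)
            grid = q.to_grid()
            for d in DIRECTIONS_2D + DIRECTIONS_3D:
                m = compute_glcm(q, d, 1, True)
                p_oracle = oracles.glcm_pairs(grid, d, 1, True)
                if m.empty:
                    assert p_oracle.sum() == 0
                    continue
                np.testing.assert_allclose(m.matrix, p_oracle, atol=1e-12)
                f = glcm_features(m)
                for name, v in f.items():
                    expected = oracles.glcm_feature(p_oracle, name)
                    assert v == pytest.approx(expected, rel=1e-10, abs=1e-10), name


class TestRunLength:
    def test_single_run_closed_forms(self):
        q = quantized(np.array([[5.0, 5.0, 5.0, 5.0]]), 2)
        f = run_length_features(q, (0, 0, 1))
        assert f["LongRunEmphasis"] == pytest.approx(16.0)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0 / 16.0)
        assert f["RunPercentage"] == pytest.approx(0.25)

    def test_all_distinct_levels_unit_runs(self):
        q = quantized(np.array([[0.0, 1.0, 2.0, 3.0]]), 4)
        f = run_length_features(q, (0, 0, 1))
        assert f["ShortRunEmphasis"] == 1.0
        assert f["LongRunEmphasis"] == 1.0
        assert f["RunPercentage"] == 1.0

    def test_checkerboard_run_length_nonuniformity(self):
        arr = np.indices((4, 4)).sum(axis=0) % 2 * 100.0
        q = quantized(arr, 2)
        f = run_length_features(q, (0, 0, 1))
        assert f["RunLengthNonuniformity"] == pytest.approx(16.0)

    def test_mask_gap_splits_runs(self):
        vol = volume_from(np.array([[1.0, 1.0, 1.0, 1.0, 1.0]]))
        mask = np.ones(vol.shape, dtype=bool)
        mask[0, 0, 2] = False  # gap: two runs of length 2
        q = quantize(vol, RoiMask(mask), 2)
        r = run_length_matrix(q, (0, 0, 1))
        assert r[0, 1] == 2  # level 1, length 2, twice

    def test_oracle_equivalence_small_rois(self, rng):
        for trial in range(3):
            arr = rng.integers(0, 4, size=(3, 5, 5)).astype(float) * 60
            vol = volume_from(arr)
            mask = RoiMask(rng.random(vol.shape) > 0.25)
            if mask.voxel_count < 4:
                continue
            q = quantize(vol, mask, 4)
            grid = q.to_grid()
            for d in DIRECTIONS_2D:
                f = run_length_features(q, d)
                runs = oracles.run_lengths(grid, d)
                for name, v in f.items():
                    expected = oracles.glrlm_feature(runs, name, q.levels.size)
                    assert v == pytest.approx(expected, rel=1e-10), (name, d)


class TestNgtdm:
    def test_constant_roi_capped_coarseness_zero_contrast(self):
        q = quantized(np.full((4, 4), 10.0), 4)
        f = nid_features(q, "2d")
        assert f["Coarseness"] == COARSENESS_CAP
        assert f["Contrast"] == 0.0

    def test_single_voxel_roi_undefined(self):
        q = quantized(np.array([[3.0]]), 2)
        assert all(np.isnan(v) for v in nid_features(q, "2d").values())

    def test_2d_equals_3d_on_single_slice(self, rng):
        arr = rng.integers(0, 200, size=(6, 6)).astype(float)
        q = quantized(arr, 6)
        f2 = nid_features(q, "2d")
        f3 = nid_features(q, "3d")
        for name in f2:
            assert f2[name] == pytest.approx(f3[name], rel=1e-12), name

    def test_checkerboard_contrast_matches_brute_force(self):
        arr = np.indices((4, 4)).sum(axis=0) % 2 * 100.0
        q = quantized(arr, 2)
        f = nid_features(q, "2d")
        expected = oracles.ngtdm_features(q.to_grid(), "2d")
        assert f["Contrast"] == pytest.approx(expected["Contrast"], rel=1e-10)

    def test_oracle_equivalence_small_rois(self, rng):
        for trial in range(3):
            arr = rng.integers(0, 5, size=(3, 5, 5)).astype(float) * 40
            vol = volume_from(arr)
            mask = RoiMask(rng.random(vol.shape) > 0.2)
            if mask.voxel_count < 6:
                continue
            q = quantize(vol, mask, 5)
            grid = q.to_grid()
            for mode in ("2d", "3d"):
                f = nid_features(q, mode)
                expected = oracles.ngtdm_features(grid, mode)
                for name, v in f.items():
                    e = expected[name]
                    if np.isnan(e):
                        assert np.isnan(v), (name, mode)
                    else:
                        assert v == pytest.approx(e, rel=1e-10, abs=1e-12), (name, mode)
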