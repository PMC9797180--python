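"""Intensity (direct, histogram, Gauss-fit) and gradient-orientation features."""
import numpy as np
import pytest

from conftest import full_mask, volume_from
from featuniq.core import ImageVolume, RoiMask
from featuniq.features.gaussfit import fit_gaussians, gauss_fit_features
from featuniq.features.gradient import gradient_orient_features
from featuniq.features.intensity import (
    intensity_direct_features,
    intensity_histogram_features,
)


class TestIntensityDirect:
    def test_constant_roi_degenerate_statistics(self):
        vol = volume_from(np.full((3, 4, 4), 50.0))
        f = intensity_direct_features(vol, full_mask(vol))
        assert f[("GlobalStd", "")] == 0.0
        assert f[("Range", "")] == 0.0
        assert f[("GlobalUniformity", "")] == 1.0
        for name in ("LocalEntropyMax", "LocalEntropyMean", "LocalEntropyMedian",
                     "LocalEntropyMin", "LocalEntropyStd"):
            assert f[(name, "")] == 0.0

    def test_order_statistics_on_1_to_100(self):
        vol = volume_from(np.arange(1.0, 101.0).reshape(10, 10))
        f = intensity_direct_features(vol, full_mask(vol))
        assert f[("GlobalMax", "")] == 100.0
        assert f[("Range", "")] == 99.0
        assert f[("GlobalMedian", "")] == 50.5

    def test_kurtosis_matches_direct_moment_ratio(self):
        values = np.array([0.0, 0.0, 0.0, 100.0])
        vol = volume_from(values.reshape(1, 4))
        f = intensity_direct_features(vol, full_mask(vol))
        mu = values.mean()
        m2 = ((values - mu) ** 2).mean()
        m4 = ((values - mu) ** 4).mean()
        assert f[("Kurtosis", "")] == pytest.approx(m4 / m2**2)

    def test_local_range_on_step_edge(self):
        arr = np.zeros((1, 3, 4))
        arr[:, :, 2:] = 100.0
        vol = volume_from(arr[0])
        f = intensity_direct_features(vol, full_mask(vol))
        assert f[("LocalRangeMax", "")] == 100.0
        assert f[("LocalRangeMin", "")] == 0.0

    def test_decile_variants_present_and_monotone(self, rng):
        vol = volume_from(rng.normal(0, 50, size=(4, 6, 6)))
        f = intensity_direct_features(vol, full_mask(vol))
        pct = [f[("Percentile", f"p{d}")] for d in range(10, 100, 10)]
        assert pct == sorted(pct)
        assert len(pct) == 9


class TestIntensityHistogram:
    def test_constant_roi_zero_range_zero_entropy(self):
        vol = volume_from(np.full((2, 3, 3), -100.0))
        f = intensity_histogram_features(vol, full_mask(vol))
        assert f[("Range", "")] == 0.0
        assert f[("Entropy", "")] == 0.0

    def test_uniform_histogram_entropy_log2_k(self):
        # 64 distinct equally-spaced values into 64 bins: one count per bin.
        vol = volume_from(np.arange(64.0).reshape(8, 8))
        f = intensity_histogram_features(vol, full_mask(vol), n_bins=64)
        assert f[("Entropy", "")] == pytest.approx(np.log2(64))
        assert f[("Uniformity", "")] == pytest.approx(1.0 / 64)

    def test_two_bin_histogram_entropy(self):
        # 1 low voxel + 3 high: probabilities (0.25, 0.75).
        vol = volume_from(np.array([[0.0, 100.0, 100.0, 100.0]]))
        f = intensity_histogram_features(vol, full_mask(vol), n_bins=2)
        assert f[("Entropy", "")] == pytest.approx(0.8113, abs=1e-4)


class TestGaussFit:
    def test_single_gaussian_parameter_recovery(self, rng):
        samples = rng.normal(0.0, 10.0, size=10_000)
        vol = volume_from(samples.reshape(10, 10, 100))
        f = gauss_fit_features(vol, full_mask(vol))
        assert f["GaussMean"] == pytest.approx(0.0, abs=1.0)
        assert f["GaussStd"] == pytest.approx(10.0, rel=0.10)
        assert f["HistArea"] == pytest.approx(
            10_000 * (samples.max() - samples.min()) / 64, rel=1e-9
        )

    def test_two_separated_gaussians_detected(self, rng):
        a = rng.normal(0.0, 5.0, size=5_000)
        b = rng.normal(50.0, 5.0, size=5_000)  # 10 sigma apart
        vol = volume_from(np.concatenate([a, b]).reshape(10, 10, 100))
        f = gauss_fit_features(vol, full_mask(vol))
        assert f["NumberOfGauss"] >= 2

    def test_deterministic_fit(self, rng):
        vol = volume_from(rng.normal(0, 20, size=(4, 5, 5)))
        f1 = gauss_fit_features(vol, full_mask(vol))
        f2 = gauss_fit_features(vol, full_mask(vol))
        assert f1 == f2

    def test_constant_roi_degenerate_fit(self):
        vol = volume_from(np.full((3, 3, 3), 40.0))
        f = gauss_fit_features(vol, full_mask(vol))
        assert f["GaussMean"] == 40.0
        assert f["GaussStd"] == 0.0
        assert f["NumberOfGauss"] == 1.0

    def test_fit_gaussians_moment_fallback_flag(self):
        centers = np.array([0.0, 1.0])
        hist = np.array([1.0, 1.0])
        params, k, fallback = fit_gaussians(centers, hist, max_components=1)
        assert k == 1
        assert params.shape == (3,)


class TestGradientOrientation:
    def test_constant_roi_all_zero(self):
        vol = volume_from(np.full((3, 5, 5), 25.0))
        f = gradient_orient_features(vol, full_mask(vol))
        assert f[("Range", "")] == 0.0
        assert f[("InterQuartileRange", "")] == 0.0

    def test_linear_ramp_single_orientation(self):
        arr = np.tile(np.arange(8.0), (8, 1))  # ramp along x: all gradients +x
        vol = volume_from(arr)
        f = gradient_orient_features(vol, full_mask(vol))
        assert f[("MedianAbsoluteDeviation", "")] == 0.0
        assert f[("Range", "")] == 0.0
        assert f[("MeanAbsoluteDeviation", "")] == 0.0

    def test_radial_blob_orientations_unskewed(self):
        y, x = np.mgrid[-20:21, -20:21].astype(float)
        blob = np.exp(-(x**2 + y**2) / 100.0) * 1000.0
        vol = volume_from(blob)
        f = gradient_orient_features(vol, full_mask(vol))
        assert abs(f[("Skewness", "")]) < 0.15
        assert f[("Range", "")] == pytest.approx(350.0, abs=10.1)


class TestUndefinedPropagation:
    def test_single_voxel_roi_flags_texture_not_firstorder(self):
        from featuniq.features.extract import extract_all

        vol = ImageVolume(np.pad(np.ones((1, 1, 1)) * 30, 1), (1, 1, 1))
        mask = np.zeros(vol.shape, dtype=bool)
        mask[1, 1, 1] = True
        fv = extract_all(vol, RoiMask(mask))
        assert np.isnan(fv[("NeighborIntensityDiff3D", "Coarseness", "")])
        assert np.isfinite(fv[("IntensityDirect", "GlobalMean", "")])
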