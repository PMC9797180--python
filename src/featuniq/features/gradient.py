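"""Gradient-orientation-histogram features.

Per slice, the in-plane intensity gradient is taken by central differences
on the full volume; at every in-mask voxel the orientation angle
atan2(gy, gx) (degrees) enters a magnitude-weighted histogram over
(-180, 180] with 10-degree bins.  The nine descriptive statistics of that
weighted orientation distribution are the features.  An all-zero gradient
field (e.g. a constant ROI) yields the degenerate convention: every
statistic is 0.
"""
from __future__ import annotations

import numpy as np

from ..core import ImageVolume, RoiMask
from .registry import DECILES

N_ANGLE_BINS = 36

GOH_STAT_NAMES = (
    "InterQuartileRange",
    "Kurtosis",
    "MeanAbsoluteDeviation",
    "MedianAbsoluteDeviation",
    "Range",
    "Skewness",
)


def orientation_histogram(volume: ImageVolume, mask: RoiMask) -> tuple[np.ndarray, np.ndarray]:
    """(bin centers in degrees, magnitude weights) of in-mask orientations."""
    mask.require_nonempty()
    mask.require_congruent(volume)
    gy = np.gradient(volume.data, axis=1)
    gx = np.gradient(volume.data, axis=2)
    gym = gy[mask.data]
    gxm = gx[mask.data]
    mag = np.hypot(gym, gxm)
    theta = np.degrees(np.arctan2(gym, gxm))  # (-180, 180]
    edges = np.linspace(-180.0, 180.0, N_ANGLE_BINS + 1)
    hist, _ = np.histogram(theta, bins=edges, weights=mag)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, hist


def _weighted_percentile(centers: np.ndarray, w: np.ndarray, frac: float) -> float:
    cum = np.cumsum(w) / w.sum()
    return float(centers[min(int(np.searchsorted(cum, frac)), centers.size - 1)])


def gradient_orient_features(
    volume: ImageVolume, mask: RoiMask
) -> dict[tuple[str, str], float]:
    """The 9 GOH features (percentile-based ones expanded over deciles)."""
    centers, w = orientation_histogram(volume, mask)
    out: dict[tuple[str, str], float] = {}
    total = w.sum()
    if total == 0:
        for name in GOH_STAT_NAMES:
            out[(name, "")] = 0.0
        for d in DECILES:
            for name in ("Percentile", "PercentileArea", "Quantile"):
                out[(name, f"p{d}")] = 0.0
        return out

    p = w / total
    mu = float((p * centers).sum())
    var = float((p * (centers - mu) ** 2).sum())
    sd = var**0.5
    skew = float((p * (centers - mu) ** 3).sum()) / sd**3 if sd > 0 else 0.0
    kurt = float((p * (centers - mu) ** 4).sum()) / var**2 if var > 0 else 0.0
    med = _weighted_percentile(centers, w, 0.5)
    nz = np.nonzero(w)[0]
    bin_width = centers[1] - centers[0]

    out[("InterQuartileRange", "")] = _weighted_percentile(centers, w, 0.75) - _weighted_percentile(centers, w, 0.25)
    out[("Kurtosis", "")] = kurt
    out[("MeanAbsoluteDeviation", "")] = float((p * np.abs(centers - mu)).sum())
    out[("MedianAbsoluteDeviation", "")] = _weighted_median_abs_dev(centers, p, med)
    out[("Range", "")] = float(centers[nz[-1]] - centers[nz[0]])
    out[("Skewness", "")] = skew
    cum = np.cumsum(w)
    for d in DECILES:
        # Percentile: linearly interpolated on the cumulative distribution;
        # Quantile: bin-centre resolution (first bin reaching the decile mass).
        out[("Percentile", f"p{d}")] = float(
            np.interp(d / 100.0 * total, cum, centers + bin_width / 2.0)
        )
        out[("Quantile", f"p{d}")] = _weighted_percentile(centers, w, d / 100.0)
        k = int(np.searchsorted(cum, d / 100.0 * total))
        out[("PercentileArea", f"p{d}")] = float(w[: min(k, w.size - 1) + 1].sum() * bin_width)
    return out


def _weighted_median_abs_dev(centers: np.ndarray, p: np.ndarray, med: float) -> float:
    dev = np.abs(centers - med)
    order = np.argsort(dev)
    cum = np.cumsum(p[order])
    return float(dev[order][min(int(np.searchsorted(cum, 0.5)), dev.size - 1)])
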