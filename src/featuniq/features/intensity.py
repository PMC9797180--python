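"""First-order intensity features: direct statistics and histogram statistics.

Direct statistics act on the raw in-mask HU values; entropy and uniformity
use a fixed equal-width histogram over the ROI's own range.  Local
statistics (entropy, range, std) are computed per voxel on a 3x3x1 in-plane
neighbourhood restricted to in-mask voxels and then summarised across
voxels (max / mean / median / min / std).

Conventions (the common radiomics defaults, recorded here because several
names admit more than one definition): kurtosis is non-excess (normal = 3);
standard deviations use the n-1 denominator; MeanAbsoluteDeviation is about
the mean, MedianAbsoluteDeviation about the median, both unscaled;
Percentile / Quantile / PercentileArea run over the decile grid 10..90.
"""
from __future__ import annotations

import numpy as np

from ..core import ImageVolume, RoiMask
from .quantize import quantize
from .registry import DECILES


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _moments(values: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, non-excess kurtosis) with population moments."""
    if weights is None:
        weights = np.ones_like(values, dtype=float)
    w = weights / weights.sum()
    mu = float((w * values).sum())
    var = float((w * (values - mu) ** 2).sum())
    if var <= 0:
        return mu, 0.0, 0.0, 0.0
    sd = var**0.5
    skew = float((w * (values - mu) ** 3).sum()) / sd**3
    kurt = float((w * (values - mu) ** 4).sum()) / var**2
    return mu, sd, skew, kurt


def _local_neighborhood_stats(
    volume: ImageVolume, mask: RoiMask, bin_labels_grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-voxel entropy/range/std over the 3x3x1 in-mask neighbourhood."""
    data = volume.data
    inside = mask.data
    coords = mask.coords()
    n = coords.shape[0]
    offsets = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    vals = np.full((len(offsets), n), np.nan)
    labs = np.full((len(offsets), n), -1, dtype=np.int64)
    shape = np.array(data.shape)
    for k, off in enumerate(offsets):
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = nb[ok]
        good = inside[idx[:, 0], idx[:, 1], idx[:, 2]]
        sel = np.zeros(n, dtype=bool)
        sel[np.nonzero(ok)[0][good]] = True
        chosen = idx[good]
        vals[k, sel] = data[chosen[:, 0], chosen[:, 1], chosen[:, 2]]
        labs[k, sel] = bin_labels_grid[chosen[:, 0], chosen[:, 1], chosen[:, 2]]

    counts = (~np.isnan(vals)).sum(axis=0)
    rng = np.nanmax(vals, axis=0) - np.nanmin(vals, axis=0)
    mean = np.nanmean(vals, axis=0)
    ssq = np.nansum((vals - mean) ** 2, axis=0)
    std = np.where(counts > 1, np.sqrt(ssq / np.maximum(counts - 1, 1)), 0.0)

    # Entropy of the neighbourhood's bin-label multiset: sort labels along
    # the window axis and count equal runs.
    slab = np.sort(labs, axis=0)
    ent = np.zeros(n)
    for kcol in range(n):
        col = slab[:, kcol]
        col = col[col >= 0]
        if col.size == 0:
            continue
        _, cnt = np.unique(col, return_counts=True)
        ent[kcol] = _entropy_bits(cnt / cnt.sum())
    return {"entropy": ent, "range": rng, "std": std}


def intensity_direct_features(
    volume: ImageVolume, mask: RoiMask, n_bins: int = 64
) -> dict[tuple[str, str], float]:
    """The 34 IntensityDirect features, percentile features expanded by decile."""
    mask.require_nonempty()
    mask.require_congruent(volume)
    v = volume.data[mask.data].astype(np.float64)
    q = quantize(volume, mask, n_bins)
    bin_grid = q.to_grid() - 1  # -1 outside mask

    hist = np.bincount(q.levels - 1, minlength=n_bins).astype(np.float64)
    p = hist / hist.sum()
    lo, hi = q.bounds
    bin_width = (hi - lo) / n_bins if hi > lo else 1.0

    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    _, _, skew, kurt = _moments(v)
    med = float(np.median(v))
    pctl = {d: float(np.percentile(v, d)) for d in DECILES}

    local = _local_neighborhood_stats(volume, mask, bin_grid)

    out: dict[tuple[str, str], float] = {}

    def put(name: str, value: float, variant: str = "") -> None:
        out[(name, variant)] = float(value)

    put("Energy", (v**2).sum())
    put("GlobalEntropy", _entropy_bits(p))
    put("GlobalMax", v.max())
    put("GlobalMean", mean)
    put("GlobalMedian", med)
    put("GlobalMin", v.min())
    put("GlobalStd", sd)
    put("GlobalUniformity", (p**2).sum())
    put("InterQuartileRange", np.percentile(v, 75) - np.percentile(v, 25))
    put("Kurtosis", kurt)
    for stat, arr in local.items():
        cap = {"entropy": "Entropy", "range": "Range", "std": "Std"}[stat]
        put(f"Local{cap}Max", arr.max())
        put(f"Local{cap}Mean", arr.mean())
        put(f"Local{cap}Median", np.median(arr))
        put(f"Local{cap}Min", arr.min())
        put(f"Local{cap}Std", arr.std(ddof=1) if arr.size > 1 else 0.0)
    put("MeanAbsoluteDeviation", np.abs(v - mean).mean())
    put("MedianAbsoluteDeviation", np.median(np.abs(v - med)))
    cum = np.cumsum(hist)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    for d in DECILES:
        put("Percentile", pctl[d], f"p{d}")
        # Quantile: centre of the first histogram bin reaching the decile mass.
        k = int(np.searchsorted(cum, d / 100.0 * hist.sum()))
        put("Quantile", centers[min(k, n_bins - 1)], f"p{d}")
        # PercentileArea: histogram area (count x bin width) at or below the decile.
        put("PercentileArea", hist[: min(k, n_bins - 1) + 1].sum() * bin_width, f"p{d}")
    put("Range", v.max() - v.min())
    put("RootMeanSquare", np.sqrt((v**2).mean()))
    put("Skewness", skew)
    put("Variance", sd**2)
    return out


def intensity_histogram_features(
    volume: ImageVolume, mask: RoiMask, n_bins: int = 64
) -> dict[tuple[str, str], float]:
    """The 9 IntensityHistogram features on the binned intensity histogram."""
    mask.require_nonempty()
    q = quantize(volume, mask, n_bins)
    hist = np.bincount(q.levels - 1, minlength=n_bins).astype(np.float64)
    p = hist / hist.sum()
    lo, hi = q.bounds
    bin_width = (hi - lo) / n_bins if hi > lo else 1.0
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    if hi == lo:
        centers = np.full(n_bins, lo)

    mu, sd, skew, kurt = _moments(centers, p)
    nz = np.nonzero(hist)[0]
    rng = float(centers[nz[-1]] - centers[nz[0]])
    cum = np.cumsum(p)

    def wquantile(frac: float) -> float:
        return float(centers[min(int(np.searchsorted(cum, frac)), n_bins - 1)])

    out: dict[tuple[str, str], float] = {
        ("Entropy", ""): _entropy_bits(p),
        ("Kurtosis", ""): kurt,
        ("Mean", ""): mu,
        ("Median", ""): wquantile(0.5),
        ("Range", ""): rng,
        ("Skewness", ""): skew,
        ("Std", ""): sd,
        ("Uniformity", ""): float((p**2).sum()),
    }
    for d in DECILES:
        out[("Percentile", f"p{d}")] = wquantile(d / 100.0)
    return out
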