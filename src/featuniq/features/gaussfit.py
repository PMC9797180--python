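"""Gaussian-mixture fit to the ROI intensity histogram.

A sum of k Gaussians (k = 1, 2, 3) is fitted to the binned histogram by
deterministic least squares (quantile-segment initialisation, bounded
Levenberg-Marquardt via scipy); the number of components is selected by a
BIC-style criterion on the residual sum of squares.  Reported are the
amplitude, area, mean and std of the dominant (largest-area) component,
the total histogram area, and the number of fitted components.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from ..core import ImageVolume, RoiMask
from .quantize import quantize

GAUSS_NAMES = ("GaussAmplitude", "GaussArea", "GaussMean", "GaussStd", "HistArea", "NumberOfGauss")


def _mixture(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for k in range(0, len(params), 3):
        a, mu, sd = params[k : k + 3]
        out += a * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))
    return out


def _initial_params(centers: np.ndarray, hist: np.ndarray, k: int) -> list[float]:
    """Quantile-segment initialisation: split the mass into k segments."""
    cum = np.cumsum(hist) / hist.sum()
    edges = np.searchsorted(cum, np.linspace(0, 1, k + 1)[1:-1])
    segs = np.split(np.arange(centers.size), edges)
    params: list[float] = []
    for seg in segs:
        w = hist[seg]
        if w.sum() <= 0:
            mu = float(centers[seg].mean()) if seg.size else float(centers.mean())
            params += [float(hist.max()), mu, float(np.ptp(centers) / (4 * k) + 1e-3)]
            continue
        mu = float((w * centers[seg]).sum() / w.sum())
        var = float((w * (centers[seg] - mu) ** 2).sum() / w.sum())
        params += [float(w.max()), mu, max(var**0.5, 1e-3)]
    return params


def fit_gaussians(
    centers: np.ndarray, hist: np.ndarray, max_components: int = 3
) -> tuple[np.ndarray, int, bool]:
    """Fit 1..max_components Gaussians; return (params, k, fallback_used)."""
    n = centers.size
    span = float(centers[-1] - centers[0]) if n > 1 else 1.0
    best: tuple[float, np.ndarray, int] | None = None
    for k in range(1, max_components + 1):
        p0 = _initial_params(centers, hist, k)
        lower = [0.0, centers[0] - span, 1e-6] * k
        upper = [hist.max() * 2 + 1e-9, centers[-1] + span, span + 1.0] * k
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _mixture, centers, hist, p0=p0, bounds=(lower, upper), maxfev=5000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(((hist - _mixture(centers, *popt)) ** 2).sum())
        bic = n * np.log(max(rss, 1e-12) / n) + 3 * k * np.log(n)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, popt, k)
    if best is None:
        # Moment fallback: single Gaussian from histogram mean and std.
        w = hist / hist.sum()
        mu = float((w * centers).sum())
        sd = max(float(((w * (centers - mu) ** 2).sum()) ** 0.5), 1e-6)
        return np.array([float(hist.max()), mu, sd]), 1, True
    return best[1], best[2], False


def gauss_fit_features(
    volume: ImageVolume, mask: RoiMask, n_bins: int = 64
) -> dict[str, float]:
    """The 6 Gauss-fit features of the ROI intensity histogram."""
    mask.require_nonempty()
    q = quantize(volume, mask, n_bins)
    hist = np.bincount(q.levels - 1, minlength=n_bins).astype(np.float64)
    lo, hi = q.bounds
    if hi == lo:
        # Degenerate single-spike histogram: delta at the constant value.
        return {
            "GaussAmplitude": float(hist.sum()),
            "GaussArea": float(hist.sum()),
            "GaussMean": lo,
            "GaussStd": 0.0,
            "HistArea": float(hist.sum()),  # unit bin width by convention
            "NumberOfGauss": 1.0,
        }
    bin_width = (hi - lo) / n_bins
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    params, k, _ = fit_gaussians(centers, hist)
    comps = params.reshape(k, 3)
    areas = comps[:, 0] * np.abs(comps[:, 2]) * np.sqrt(2 * np.pi)
    dom = int(np.argmax(areas))
    return {
        "GaussAmplitude": float(comps[dom, 0]),
        "GaussArea": float(areas[dom]),
        "GaussMean": float(comps[dom, 1]),
        "GaussStd": float(abs(comps[dom, 2])),
        "HistArea": float(hist.sum() * bin_width),
        "NumberOfGauss": float(k),
    }
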