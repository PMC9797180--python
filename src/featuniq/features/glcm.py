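"""Gray-level co-occurrence matrices and the 22 Haralick-lineage features.

A GLCM is the second-order joint probability p(i, j) of observing gray
levels i and j at the two ends of a fixed offset vector, both endpoints
inside the ROI.  2D matrices use in-plane offsets, so pair counts pool
across slices automatically before normalization.  All entropies are in
bits with the 0·log 0 = 0 convention.

IDMN and IDN normalize the gray-level difference by the number of discrete
levels N_g: IDN divides |i−j| by N_g and IDMN divides (i−j)² by N_g²,
which drives both toward 1 as N_g grows — the mechanism that makes them
insensitive to the underlying tissue.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .quantize import QuantizedRoi

_LOG2E = math.log2(math.e)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


@dataclass(frozen=True)
class Glcm:
    matrix: np.ndarray  # (N_g, N_g), probabilities
    direction: tuple[int, int, int]
    distance: int
    symmetric: bool
    n_pairs: int

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def compute_glcm(
    q: QuantizedRoi,
    direction: tuple[int, int, int],
    distance: int = 1,
    symmetric: bool = True,
) -> Glcm:
    """Pair-probability matrix along one offset; explicitly empty if no pairs."""
    ng = q.n_levels
    grid = q.to_grid()
    off = np.asarray(direction) * distance
    # Overlap slices: pairs (v, v + off) with both endpoints on the grid.
    src = []
    dst = []
    for ax in range(3):
        o = int(off[ax])
        n = grid.shape[ax]
        if abs(o) >= n:
            return Glcm(np.zeros((ng, ng)), tuple(direction), distance, symmetric, 0)
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    a = grid[tuple(src)]
    b = grid[tuple(dst)]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return Glcm(np.zeros((ng, ng)), tuple(direction), distance, symmetric, 0)
    ai = a[ok] - 1
    bi = b[ok] - 1
    counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    n_pairs = int(ok.sum())
    if symmetric:
        counts = counts + counts.T
    return Glcm(counts / counts.sum(), tuple(direction), distance, symmetric, n_pairs)


def glcm_features(m: Glcm) -> dict[str, float]:
    """The 22 co-occurrence features; all NaN on an explicitly-empty matrix."""
    names = (
        "Autocorrelation ClusterProminence ClusterShade ClusterTendency Contrast "
        "Correlation DifferenceEntropy Dissimilarity Energy Entropy "
        "InformationMeasureCorr1 InformationMeasureCorr2 InverseDiff InverseDiffMoment "
        "InverseDiffMomentNorm InverseDiffNorm InverseVariance MaxProbability "
        "SumAverage SumEntropy SumVariance Variance"
    ).split()
    if m.empty:
        return {name: float("nan") for name in names}

    p = m.matrix
    ng = m.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = math.sqrt(max(float(((i - mu_x) ** 2 * px).sum()), 0.0))
    sd_y = math.sqrt(max(float(((i - mu_y) ** 2 * py).sum()), 0.0))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).ravel()
    kdiff = np.abs(ii - jj).ravel()
    p_sum = np.bincount(ksum, weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff, weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1)
    k_diff = np.arange(ng)

    diff = ii - jj
    absdiff = np.abs(diff)
    dev = ii + jj - mu_x - mu_y

    hxy = _entropy_bits(p.ravel())
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    autocorr = float((ii * jj * p).sum())
    corr = float("nan")
    if sd_x > 0 and sd_y > 0:
        corr = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    imc1 = float("nan")
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy) / _LOG2E), 0.0))

    sum_avg = float((k_sum * p_sum).sum())
    off_diag = absdiff > 0
    inv_var = float((p[off_diag] / (diff[off_diag] ** 2)).sum())

    out = {
        "Autocorrelation": autocorr,
        "ClusterProminence": float((dev**4 * p).sum()),
        "ClusterShade": float((dev**3 * p).sum()),
        "ClusterTendency": float((dev**2 * p).sum()),
        "Contrast": float((diff**2 * p).sum()),
        "Correlation": corr,
        "DifferenceEntropy": _entropy_bits(p_diff),
        "Dissimilarity": float((absdiff * p).sum()),
        "Energy": float((p**2).sum()),
        "Entropy": hxy,
        "InformationMeasureCorr1": imc1,
        "InformationMeasureCorr2": imc2,
        "InverseDiff": float((p / (1.0 + absdiff)).sum()),
        "InverseDiffMoment": float((p / (1.0 + diff**2)).sum()),
        "InverseDiffMomentNorm": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "InverseDiffNorm": float((p / (1.0 + absdiff / ng)).sum()),
        "InverseVariance": inv_var,
        "MaxProbability": float(p.max()),
        "SumAverage": sum_avg,
        "SumEntropy": _entropy_bits(p_sum),
        "SumVariance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "Variance": float(((ii - mu_x) ** 2 * p).sum()),
    }
    assert set(out) == set(names)
    return out
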