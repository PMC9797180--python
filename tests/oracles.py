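"""Independent brute-force oracles for texture features.

Everything here is written as plain enumeration over voxels — no shared
code with the package implementation — and is only meant for tiny ROIs.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def glcm_pairs(grid: np.ndarray, direction, distance=1, symmetric=True) -> np.ndarray:
    """Count co-occurrence pairs by looping over every voxel."""
    ng = int(grid.max())
    mat = np.zeros((ng, ng))
    off = tuple(int(d) * distance for d in direction)
    for idx in np.ndindex(grid.shape):
        a = grid[idx]
        if a == 0:
            continue
        jdx = tuple(i + o for i, o in zip(idx, off))
        if any(j < 0 or j >= s for j, s in zip(jdx, grid.shape)):
            continue
        b = grid[jdx]
        if b == 0:
            continue
        mat[a - 1, b - 1] += 1
        if symmetric:
            mat[b - 1, a - 1] += 1
    if mat.sum() > 0:
        mat /= mat.sum()
    return mat


def glcm_feature(p: np.ndarray, name: str) -> float:
    """Direct evaluation of one co-occurrence feature from its formula."""
    ng = p.shape[0]
    tot = 0.0
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    def h(probs):
        return -sum(q * math.log2(q) for q in probs if q > 0)

    if name == "Energy":
        return float((p**2).sum())
    if name == "Entropy":
        return h(p.ravel())
    if name == "MaxProbability":
        return float(p.max())
    if name == "Autocorrelation":
        return sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    if name == "Contrast":
        return sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if name == "Dissimilarity":
        return sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    if name == "InverseDiff":
        return sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    if name == "InverseDiffMoment":
        return sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    if name == "InverseDiffNorm":
        return sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    if name == "InverseDiffMomentNorm":
        return sum(p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    if name == "InverseVariance":
        return sum(p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j)
    if name == "Correlation":
        return (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sd_x * sd_y)
    if name == "Variance":
        return sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if name in ("ClusterTendency", "ClusterShade", "ClusterProminence"):
        k = {"ClusterTendency": 2, "ClusterShade": 3, "ClusterProminence": 4}[name]
        return sum(
            (i + 1 + j + 1 - mu_x - mu_y) ** k * p[i, j]
            for i in range(ng)
            for j in range(ng)
        )
    if name in ("SumAverage", "SumEntropy", "SumVariance"):
        psum = {}
        for i in range(ng):
            for j in range(ng):
                psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
        sa = sum(k * v for k, v in psum.items())
        if name == "SumAverage":
            return sa
        if name == "SumEntropy":
            return h(psum.values())
        return sum((k - sa) ** 2 * v for k, v in psum.items())
    if name == "DifferenceEntropy":
        pdiff = {}
        for i in range(ng):
            for j in range(ng):
                pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
        return h(pdiff.values())
    if name in ("InformationMeasureCorr1", "InformationMeasureCorr2"):
        hxy = h(p.ravel())
        hxy1 = -sum(
            p[i, j] * math.log2(px[i] * py[j])
            for i in range(ng)
            for j in range(ng)
            if p[i, j] > 0 and px[i] * py[j] > 0
        )
        hxy2 = h([px[i] * py[j] for i in range(ng) for j in range(ng)])
        if name == "InformationMeasureCorr1":
            return (hxy - hxy1) / max(h(px), h(py))
        ln2 = math.log(2.0)
        return math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy) * ln2), 0.0))
    raise KeyError(name)


def run_lengths(grid: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Enumerate maximal runs by walking every lattice line voxel by voxel."""
    runs: dict[tuple[int, int], int] = {}
    d = np.asarray(direction)
    starts = [
        idx
        for idx in np.ndindex(grid.shape)
        if any(
            (np.asarray(idx) - d)[k] < 0 or (np.asarray(idx) - d)[k] >= grid.shape[k]
            for k in range(3)
        )
    ]
    for s in starts:
        pos = np.asarray(s)
        current, length = 0, 0
        while all(0 <= pos[k] < grid.shape[k] for k in range(3)):
            lvl = int(grid[tuple(pos)])
            if lvl == current:
                length += 1
            else:
                if current > 0:
                    runs[(current, length)] = runs.get((current, length), 0) + 1
                current, length = lvl, 1
            pos = pos + d
        if current > 0:
            runs[(current, length)] = runs.get((current, length), 0) + 1
    return runs


def glrlm_feature(runs: dict[tuple[int, int], int], name: str, n_vox: int) -> float:
    nr = sum(runs.values())
    if name == "ShortRunEmphasis":
        return sum(c / l**2 for (_, l), c in runs.items()) / nr
    if name == "LongRunEmphasis":
        return sum(c * l**2 for (_, l), c in runs.items()) / nr
    if name == "GrayLevelNonuniformity":
        per_level: dict[int, int] = {}
        for (i, _), c in runs.items():
            per_level[i] = per_level.get(i, 0) + c
        return sum(v**2 for v in per_level.values()) / nr
    if name == "RunLengthNonuniformity":
        per_len: dict[int, int] = {}
        for (_, l), c in runs.items():
            per_len[l] = per_len.get(l, 0) + c
        return sum(v**2 for v in per_len.values()) / nr
    if name == "RunPercentage":
        return nr / n_vox
    if name == "LowGrayLevelRunEmpha":
        return sum(c / i**2 for (i, _), c in runs.items()) / nr
    if name == "HighGrayLevelRunEmpha":
        return sum(c * i**2 for (i, _), c in runs.items()) / nr
    if name == "ShortRunLowGrayLevelEmpha":
        return sum(c / (i**2 * l**2) for (i, l), c in runs.items()) / nr
    if name == "ShortRunHighGrayLevelEmpha":
        return sum(c * i**2 / l**2 for (i, l), c in runs.items()) / nr
    if name == "LongRunLowGrayLevelEmpha":
        return sum(c * l**2 / i**2 for (i, l), c in runs.items()) / nr
    if name == "LongRunHighGrayLevelEmpha":
        return sum(c * i**2 * l**2 for (i, l), c in runs.items()) / nr
    raise KeyError(name)


def ngtdm_features(grid: np.ndarray, mode: str) -> dict[str, float]:
    """Direct NGTDM evaluation with explicit voxel loops."""
    ng = int(grid.max())
    if mode == "2d":
        offsets = [
            (0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
        ]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    s = np.zeros(ng)
    n_i = np.zeros(ng, dtype=int)
    for idx in np.ndindex(grid.shape):
        lvl = int(grid[idx])
        if lvl == 0:
            continue
        nb = []
        for off in offsets:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= sdim for j, sdim in zip(jdx, grid.shape)):
                continue
            if grid[jdx] > 0:
                nb.append(int(grid[jdx]))
        if not nb:
            continue
        s[lvl - 1] += abs(lvl - sum(nb) / len(nb))
        n_i[lvl - 1] += 1
    n = int(n_i.sum())
    p = n_i / n
    present = [i for i in range(ng) if p[i] > 0]
    npres = len(present)
    eps = 1e-6
    out = {"Coarseness": 1.0 / max(float((p * s).sum()), eps)}
    contrast = 0.0
    if npres > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (npres * (npres - 1))
            * s.sum()
            / n
        )
    out["Contrast"] = contrast
    den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    out["Busyness"] = float((p * s).sum()) / den if den > 0 else float("nan")
    comp = 0.0
    stren = 0.0
    if npres > 1:
        comp = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / n
        )
        stren = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        ) / max(float(s.sum()), eps)
    out["Complexity"] = comp
    out["Strength"] = stren
    return out
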