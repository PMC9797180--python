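"""Neighborhood gray-tone difference matrix features.

For every in-mask voxel the absolute difference between its gray level and
the mean level of its in-mask neighbours (8-neighbourhood in 2D, 26 in 3D)
is accumulated per level into s(i); with level occupancy probabilities p(i)
these yield Coarseness, Contrast, Busyness, Complexity and Strength.
Coarseness uses an epsilon-guarded denominator (1e-6), capping its value on
perfectly homogeneous regions at 1e6.
"""
from __future__ import annotations

import itertools

import numpy as np

from .quantize import QuantizedRoi

EPS = 1e-6
COARSENESS_CAP = 1.0 / EPS

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _neighbor_offsets(mode: str) -> list[tuple[int, int, int]]:
    if mode == "2d":
        return [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    if mode == "3d":
        return [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")


def ngtdm(q: QuantizedRoi, mode: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (s, n_i, N) where s(i) sums |i - mean neighbour level|.

    Voxels without any in-mask neighbour are excluded from both s and n.
    """
    grid = q.to_grid()
    ng = q.n_levels
    inside = grid > 0
    nb_sum = np.zeros(grid.shape, dtype=np.float64)
    nb_cnt = np.zeros(grid.shape, dtype=np.int64)
    for off in _neighbor_offsets(mode):
        sl_src, sl_dst = [], []
        for ax, o in enumerate(off):
            n = grid.shape[ax]
            if o >= 0:
                sl_src.append(slice(0, n - o))
                sl_dst.append(slice(o, n))
            else:
                sl_src.append(slice(-o, n))
                sl_dst.append(slice(0, n + o))
        sl_src, sl_dst = tuple(sl_src), tuple(sl_dst)
        contrib = np.zeros(grid.shape)
        cnt = np.zeros(grid.shape, dtype=np.int64)
        contrib[sl_dst] = np.where(inside[sl_src], grid[sl_src], 0)
        cnt[sl_dst] = inside[sl_src]
        nb_sum += contrib
        nb_cnt += cnt

    use = inside & (nb_cnt > 0)
    levels = grid[use]
    diffs = np.abs(levels - nb_sum[use] / nb_cnt[use])
    s = np.zeros(ng)
    np.add.at(s, levels - 1, diffs)
    n_i = np.bincount(levels - 1, minlength=ng)
    return s, n_i, int(use.sum())


def nid_features(q: QuantizedRoi, mode: str) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength for one mode."""
    s, n_i, n = ngtdm(q, mode)
    if n == 0:  # e.g. single-voxel ROI: no neighbourhood exists
        return {k: float("nan") for k in NGTDM_NAMES}
    ng = len(s)
    p = n_i / n
    present = p > 0
    n_p = int(present.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    coarse = 1.0 / max(float((p * s).sum()), EPS)

    contrast = 0.0
    if n_p > 1:
        pi = p[present]
        iv = i[present]
        contrast = (
            float((pi[:, None] * pi[None, :] * (iv[:, None] - iv[None, :]) ** 2).sum())
            / (n_p * (n_p - 1))
            * float(s.sum())
            / n
        )

    ipi = i[present] * p[present]
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = float((p * s).sum()) / busy_den if busy_den > 0 else float("nan")

    complexity = 0.0
    strength = 0.0
    if n_p > 1:
        pi = p[present]
        si = s[present]
        iv = i[present]
        dd = np.abs(iv[:, None] - iv[None, :])
        num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        den = pi[:, None] + pi[None, :]
        complexity = float((dd * num / den).sum()) / n
        strength = float((den * (iv[:, None] - iv[None, :]) ** 2).sum()) / max(
            float(s.sum()), EPS
        )

    return {
        "Busyness": busyness,
        "Coarseness": coarse,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
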