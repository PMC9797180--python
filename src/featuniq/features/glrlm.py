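"""Gray-level run-length matrix and its 11 standard features.

Runs are maximal sequences of equal gray level along a direction,
restricted to in-mask voxels (a gap in the mask terminates a run).
In-plane directions are evaluated per slice and the run counts pooled
across slices before the features are computed.
"""
from __future__ import annotations

import numpy as np

from ..core import FeatuniqError
from .quantize import QuantizedRoi


def _iter_lines(grid: np.ndarray, direction: tuple[int, int, int]):
    """Yield every maximal 1D lattice line of ``grid`` along ``direction``.

    Supports the in-plane directions (0,0,1), (0,1,0), (0,1,±1) and their
    3D analogues with |components| <= 1.
    """
    dz, dy, dx = direction
    if (dz, dy, dx) == (0, 0, 1):
        for sl in grid:
            yield from sl
    elif (dz, dy, dx) == (0, 1, 0):
        for sl in grid:
            yield from sl.T
    elif dz == 0 and dy == 1 and dx in (1, -1):
        for sl in grid:
            s = sl if dx == 1 else sl[:, ::-1]
            ny, nx = s.shape
            for off in range(-ny + 1, nx):
                yield np.diagonal(s, offset=off)
    else:
        raise FeatuniqError(f"unsupported run-length direction {direction}")


def run_length_matrix(q: QuantizedRoi, direction: tuple[int, int, int]) -> np.ndarray:
    """(N_g, L_max) run counts r(level, length) along one direction."""
    grid = q.to_grid()
    # Crop to the ROI bounding box: runs cannot cross the all-zero exterior.
    lo = q.coords.min(axis=0)
    hi = q.coords.max(axis=0) + 1
    grid = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    max_len = max(grid.shape)
    r = np.zeros((q.n_levels, max_len), dtype=np.int64)
    for line in _iter_lines(grid, direction):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # Split at level changes; 0 (outside mask) terminates runs.
        change = np.nonzero(np.diff(line))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            lvl = line[s]
            if lvl > 0:
                r[lvl - 1, e - s - 1] += 1
    return r


def run_length_features(q: QuantizedRoi, direction: tuple[int, int, int]) -> dict[str, float]:
    """The 11 standard GLRLM features from the pooled run-length matrix."""
    r = run_length_matrix(q, direction).astype(np.float64)
    nr = r.sum()
    n_vox = q.levels.size
    if nr == 0:
        return {k: float("nan") for k in _NAMES}
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(np.float64)
    l = np.arange(1, r.shape[1] + 1)[None, :].astype(np.float64)
    r_i = r.sum(axis=1)
    r_l = r.sum(axis=0)
    out = {
        "ShortRunEmphasis": float((r / l**2).sum() / nr),
        "LongRunEmphasis": float((r * l**2).sum() / nr),
        "GrayLevelNonuniformity": float((r_i**2).sum() / nr),
        "RunLengthNonuniformity": float((r_l**2).sum() / nr),
        "RunPercentage": float(nr / n_vox),
        "LowGrayLevelRunEmpha": float((r / i**2).sum() / nr),
        "HighGrayLevelRunEmpha": float((r * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmpha": float((r / (i**2 * l**2)).sum() / nr),
        "ShortRunHighGrayLevelEmpha": float((r * i**2 / l**2).sum() / nr),
        "LongRunLowGrayLevelEmpha": float((r * l**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmpha": float((r * i**2 * l**2).sum() / nr),
    }
    return out


_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonuniformity",
    "RunLengthNonuniformity",
    "RunPercentage",
    "LowGrayLevelRunEmpha",
    "HighGrayLevelRunEmpha",
    "ShortRunLowGrayLevelEmpha",
    "ShortRunHighGrayLevelEmpha",
    "LongRunLowGrayLevelEmpha",
    "LongRunHighGrayLevelEmpha",
)
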