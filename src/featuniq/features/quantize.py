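"""Gray-level quantization of an ROI.

Equal-width binning of the ROI's own [min, max] HU range into N_g levels
(1..N_g), half-open bins with the maximum assigned to the top level.
A constant ROI maps entirely to level 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import FeatuniqError, ImageVolume, RoiMask


@dataclass(frozen=True)
class QuantizedRoi:
    coords: np.ndarray  # (n, 3) int voxel coordinates (z, y, x)
    levels: np.ndarray  # (n,) int gray levels in 1..n_levels
    n_levels: int
    bounds: tuple[float, float]  # (min, max) HU used for the binning
    shape: tuple[int, int, int]  # grid shape of the source volume

    def to_grid(self) -> np.ndarray:
        """Dense int grid with gray levels in the mask and 0 outside."""
        grid = np.zeros(self.shape, dtype=np.int32)
        grid[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = self.levels
        return grid


def quantize(volume: ImageVolume, mask: RoiMask, n_levels: int = 64) -> QuantizedRoi:
    mask.require_nonempty()
    mask.require_congruent(volume)
    if n_levels < 2:
        raise FeatuniqError(f"n_levels must be >= 2, got {n_levels}")
    coords = mask.coords()
    values = volume.data[mask.data]
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        levels = np.ones(values.shape, dtype=np.int64)
    else:
        levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        np.clip(levels, 1, n_levels, out=levels)
    return QuantizedRoi(
        coords=coords,
        levels=levels,
        n_levels=int(n_levels),
        bounds=(lo, hi),
        shape=volume.shape,
    )
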