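"""Core in-memory containers for CT volumes and voxel masks.

Arrays use the (slice, row, column) = (z, y, x) axis convention with
0-based indices; "in-plane" always means a fixed slice index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FeatuniqError(Exception):
    """Base class for package errors."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar field in Hounsfield units.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel intensities in HU. Must be finite.
    spacing : tuple of float
        Voxel spacing in mm per axis, ordered (z, y, x). Strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise FeatuniqError(f"volume must be 3D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FeatuniqError("volume contains non-finite HU values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise FeatuniqError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiMask:
    """A binary 3D voxel mask congruent with an :class:`ImageVolume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FeatuniqError(f"mask must be 3D, got shape {arr.shape}")
        object.__setattr__(self, "data", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def bounding_box(self) -> tuple[slice, slice, slice]:
        """Tight bounding box as a tuple of slices; raises on an empty mask."""
        if self.voxel_count == 0:
            raise FeatuniqError("empty mask has no bounding box")
        idx = np.nonzero(self.data)
        return tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in idx)

    def coords(self) -> np.ndarray:
        """Foreground voxel coordinates as an (n, 3) int array in (z, y, x)."""
        return np.argwhere(self.data)

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise FeatuniqError("operation requires a non-empty ROI mask")

    def require_congruent(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise FeatuniqError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def relative_coords(mask: RoiMask) -> np.ndarray:
    """Foreground coordinates relative to the bounding-box corner.

    Two masks are rigid translations of each other iff these arrays are
    identical (row order is lexicographic, hence canonical).
    """
    c = mask.coords()
    return c - c.min(axis=0)
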