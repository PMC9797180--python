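"""Rigid translocation of the tumor ROI into other tissue regions.

The tumor mask is translated (no rotation, no rescaling) so that every
foreground voxel lands inside the target tissue of the label map.  In-plane
offsets (z-shift 0) are preferred; only when no in-plane offset fully
contains the translated mask does the search widen to |dz| = 1, 2, ...
Among all valid offsets of the winning tier one is drawn uniformly at
random under the caller's seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import FeatuniqError, RoiMask, relative_coords
from .phantom import TISSUE_LABELS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Placement:
    """One shape-preserved copy of the tumor ROI inside a target tissue."""

    tissue: str
    offset: tuple[int, int, int]  # voxel shift (z, y, x) applied to the tumor ROI
    mask: RoiMask
    used_z_fallback: bool


def _valid_offsets(tumor: RoiMask, target: np.ndarray) -> np.ndarray:
    """All integer offsets d with (tumor + d) entirely inside ``target``.

    Returns an (m, 3) int array of (dz, dy, dx).  Computed by FFT
    cross-correlation of the target indicator with the bbox-cropped tumor
    kernel: an anchor position is valid iff the overlap count equals the
    tumor voxel count.
    """
    bbox = tumor.bounding_box
    kernel = tumor.data[bbox].astype(np.float64)
    n = tumor.voxel_count
    corr = fftconvolve(target.astype(np.float64), kernel[::-1, ::-1, ::-1], mode="valid")
    counts = np.rint(corr).astype(np.int64)
    anchors = np.argwhere(counts == n)  # anchor = bbox-corner position of the shifted ROI
    corner = np.array([s.start for s in bbox])
    return anchors - corner


def translate_mask(tumor: RoiMask, offset: np.ndarray) -> RoiMask:
    out = np.zeros(tumor.shape, dtype=bool)
    coords = tumor.coords() + np.asarray(offset)
    out[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    return RoiMask(out)


def find_placements(
    tumor: RoiMask,
    labels: np.ndarray,
    targets: list[str],
    seed: int,
) -> list[Placement]:
    """Place the tumor ROI into each target tissue of the label map.

    Unplaceable tissues are omitted from the result with a logged warning;
    the caller decides whether to drop the patient or relax requirements.
    """
    tumor.require_nonempty()
    if labels.shape != tumor.shape:
        raise FeatuniqError(
            f"label map shape {labels.shape} does not match tumor mask {tumor.shape}"
        )
    if not targets:
        raise FeatuniqError("targets must be non-empty")

    placements: list[Placement] = []
    for tissue in targets:
        if tissue not in TISSUE_LABELS:
            raise FeatuniqError(f"unknown tissue {tissue!r}")
        target = labels == TISSUE_LABELS[tissue]
        offsets = _valid_offsets(tumor, target)
        if offsets.size == 0:
            log.warning("tissue %s: no valid placement at any z-offset", tissue)
            continue
        rng = np.random.default_rng([int(seed), TISSUE_LABELS[tissue]])
        in_plane = offsets[offsets[:, 0] == 0]
        if in_plane.shape[0] > 0:
            pool, fallback = in_plane, False
        else:
            min_dz = np.abs(offsets[:, 0]).min()
            pool, fallback = offsets[np.abs(offsets[:, 0]) == min_dz], True
        # Canonical ordering (argwhere is already lexicographic) keeps the
        # uniform draw reproducible across platforms.
        choice = pool[rng.integers(pool.shape[0])]
        mask = translate_mask(tumor, choice)
        assert np.array_equal(relative_coords(mask), relative_coords(tumor))
        placements.append(
            Placement(
                tissue=tissue,
                offset=tuple(int(v) for v in choice),
                mask=mask,
                used_z_fallback=fallback,
            )
        )
    return placements
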