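"""Deterministic synthetic CT phantoms with five labelled tissue classes.

The phantom is a slab geometry: four axial-plane bands (muscle, adipose,
heart, lung) stacked along the row (y) axis, constant along z, with a
spherical lung nodule embedded in the lung band.  The geometry is not
anatomically realistic; it only has to provide five disjoint regions, each
large enough to host the nodule-shaped ROI, with distinct mean attenuation
and tunable texture so that co-occurrence and difference statistics are
non-degenerate.

Texture model: zero-mean Gaussian white noise smoothed by a Gaussian kernel
whose width is the spatial correlation length, rescaled to the requested
standard deviation, then added to the tissue mean.  Per tissue region the
empirical noise mean is removed, so each region's voxel mean equals the
specified attenuation exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import FeatuniqError, ImageVolume, RoiMask

#: Integer labels of the five tissue classes in the label map.
TISSUE_LABELS: dict[str, int] = {
    "lung": 1,
    "adipose": 2,
    "heart": 3,
    "muscle": 4,
    "nodule": 5,
}

#: Tissues the tumor ROI is translocated into.
NON_TUMOR_TISSUES: tuple[str, ...] = ("adipose", "heart", "lung", "muscle")

# Fractional row bands of the slab layout: tissue -> (y_lo, y_hi).
_BANDS: dict[str, tuple[float, float]] = {
    "muscle": (0.00, 0.22),
    "adipose": (0.22, 0.44),
    "heart": (0.44, 0.66),
    "lung": (0.66, 1.00),
}


@dataclass(frozen=True)
class TissueParams:
    """Attenuation and texture of one tissue class."""

    mean_hu: float
    noise_sigma: float  # HU, standard deviation of the stationary texture
    corr_length: float  # voxels, Gaussian smoothing sigma


def default_tissues() -> dict[str, TissueParams]:
    """Textbook attenuation means with moderate, tissue-specific texture."""
    return {
        "lung": TissueParams(-800.0, 60.0, 1.5),
        "adipose": TissueParams(-100.0, 20.0, 1.0),
        "heart": TissueParams(40.0, 25.0, 1.2),
        "muscle": TissueParams(50.0, 25.0, 1.0),
        "nodule": TissueParams(20.0, 40.0, 1.2),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic patient scan.

    Same spec + same seed produce a bit-identical phantom.
    """

    shape: tuple[int, int, int] = (48, 96, 96)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    tissues: dict[str, TissueParams] = field(default_factory=default_tissues)
    nodule_diameter_mm: float = 12.0
    nodule_rim_delta_hu: float = -30.0  # intensity ramp from centre to rim
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 16 for n in self.shape):
            raise FeatuniqError(f"all grid dimensions must be >= 16 voxels, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise FeatuniqError(f"voxel spacing must be positive, got {self.spacing}")
        if self.nodule_diameter_mm <= 0:
            raise FeatuniqError("nodule diameter must be positive")
        missing = set(TISSUE_LABELS) - set(self.tissues)
        if missing:
            raise FeatuniqError(f"missing tissue parameters for {sorted(missing)}")
        means = [self.tissues[t].mean_hu for t in TISSUE_LABELS]
        if len(set(means)) != len(means):
            raise FeatuniqError("tissue mean attenuations must be pairwise distinct")


@dataclass(frozen=True)
class LabeledPhantom:
    """A phantom volume with its tissue-label map and nodule ROI."""

    volume: ImageVolume
    labels: np.ndarray  # int label per voxel, same shape as volume
    nodule_mask: RoiMask

    def __post_init__(self) -> None:
        if self.labels.shape != self.volume.shape:
            raise FeatuniqError("label map and volume shapes differ")
        if self.nodule_mask.shape != self.volume.shape:
            raise FeatuniqError("nodule mask and volume shapes differ")


def _label_map(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the label map and the nodule sphere mask."""
    nz, ny, nx = spec.shape
    labels = np.empty(spec.shape, dtype=np.int16)
    for tissue, (lo, hi) in _BANDS.items():
        y0, y1 = int(round(lo * ny)), int(round(hi * ny))
        labels[:, y0:y1, :] = TISSUE_LABELS[tissue]

    # Nodule sphere centred in the lung band.
    lung_lo, lung_hi = _BANDS["lung"]
    centre = np.array(
        [nz / 2.0, (lung_lo + lung_hi) / 2.0 * ny, nx / 2.0]
    )
    radius_mm = spec.nodule_diameter_mm / 2.0
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    d2 = (
        ((zz + 0.5 - centre[0]) * spec.spacing[0]) ** 2
        + ((yy + 0.5 - centre[1]) * spec.spacing[1]) ** 2
        + ((xx + 0.5 - centre[2]) * spec.spacing[2]) ** 2
    )
    sphere = d2 <= radius_mm**2
    if sphere.sum() == 0:
        raise FeatuniqError("nodule diameter below voxel size: empty nodule")
    if np.any(labels[sphere] != TISSUE_LABELS["lung"]):
        raise FeatuniqError(
            f"nodule of diameter {spec.nodule_diameter_mm} mm does not fit "
            "entirely inside the lung region of this grid"
        )
    labels[sphere] = TISSUE_LABELS["nodule"]
    return labels, sphere


def generate_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Render a labelled phantom volume; pure function of the spec (incl. seed)."""
    labels, sphere = _label_map(spec)
    rng = np.random.default_rng(spec.seed)
    data = np.zeros(spec.shape, dtype=np.float64)

    # One smoothed noise field per tissue, drawn in fixed label order so the
    # output is independent of dict ordering quirks.
    for tissue in sorted(TISSUE_LABELS, key=TISSUE_LABELS.get):
        params = spec.tissues[tissue]
        region = labels == TISSUE_LABELS[tissue]
        field_vals = np.full(spec.shape, params.mean_hu)
        if params.noise_sigma > 0:
            noise = rng.standard_normal(spec.shape)
            if params.corr_length > 0:
                noise = gaussian_filter(noise, params.corr_length, mode="reflect")
            sd = noise.std()
            if sd > 0:
                noise *= params.noise_sigma / sd
            # Remove the regional noise mean: region mean == mean_hu exactly.
            noise_region = noise[region]
            field_vals = field_vals + noise - noise_region.mean()
        data[region] = field_vals[region]

    # Radial intensity ramp inside the nodule (centre -> rim), which makes
    # gradient-orientation features non-degenerate.
    if spec.nodule_rim_delta_hu != 0.0:
        coords = np.argwhere(sphere)
        centre = coords.mean(axis=0)
        r = np.sqrt(((coords - centre) ** 2).sum(axis=1))
        rmax = r.max() if r.max() > 0 else 1.0
        ramp = r / rmax
        # Mean-centred ramp so the nodule's voxel mean stays at its spec value.
        data[sphere] += spec.nodule_rim_delta_hu * (ramp - ramp.mean())

    volume = ImageVolume(data, spec.spacing)
    return LabeledPhantom(volume=volume, labels=labels, nodule_mask=RoiMask(sphere))
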