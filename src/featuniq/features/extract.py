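"""Orchestration: compute every registry feature for one (volume, mask) pair.

No resampling, filtering or HU windowing is applied before extraction; 2D
categories are computed with in-plane offsets (pair/run counts pooled
across slices), 3D categories on the full ROI.  Features that are
genuinely undefined on an input (e.g. texture features of a single-voxel
ROI) are carried as NaN, never silently zero; downstream statistics skip
them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import FeatuniqError, ImageVolume, RoiMask
from . import registry as reg
from .gaussfit import gauss_fit_features
from .glcm import compute_glcm, glcm_features
from .glrlm import run_length_features
from .gradient import gradient_orient_features
from .intensity import intensity_direct_features, intensity_histogram_features
from .ngtdm import nid_features
from .quantize import quantize


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable extraction parameters (defaults are the package's conventions)."""

    n_gray_levels: int = 64  # texture-matrix quantization
    n_histogram_bins: int = 64  # first-order histogram features
    glcm_distance: int = 1
    glcm_symmetric: bool = True


@dataclass
class FeatureVector:
    """Mapping (category, feature, variant) -> scalar value for one ROI."""

    values: dict[tuple[str, str, str], float]
    roi_id: str = ""
    params: ExtractionParams = field(default_factory=ExtractionParams)

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)

    def feature_mean(self, category: str, name: str) -> float:
        """Mean over variants (NaN-skipping); the per-feature scalar summary."""
        vals = np.array(
            [v for (c, f, _), v in self.values.items() if c == category and f == name]
        )
        if vals.size == 0:
            raise KeyError((category, name))
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")

    def variant_values(self, category: str, name: str) -> dict[str, float]:
        return {
            var: v for (c, f, var), v in self.values.items() if c == category and f == name
        }

    def to_frame(self, patient: str = "", tissue_region: str = "") -> pd.DataFrame:
        rows = [
            {
                "patient": patient,
                "tissue_region": tissue_region,
                "category": c,
                "feature": f,
                "variant": var,
                "value": v,
            }
            for (c, f, var), v in self.values.items()
        ]
        return pd.DataFrame(rows, columns=["patient", "tissue_region", "category", "feature", "variant", "value"])


def extract_all(
    volume: ImageVolume,
    mask: RoiMask,
    registry: reg.FeatureRegistry | None = None,
    params: ExtractionParams | None = None,
    roi_id: str = "",
) -> FeatureVector:
    """One value per (feature, variant) of the registry expansion."""
    registry = registry or reg.default_registry()
    params = params or ExtractionParams()
    mask.require_nonempty()
    mask.require_congruent(volume)

    values: dict[tuple[str, str, str], float] = {}

    direct = intensity_direct_features(volume, mask, params.n_histogram_bins)
    for (name, var), v in direct.items():
        values[(reg.INTENSITY_DIRECT, name, var)] = v

    histo = intensity_histogram_features(volume, mask, params.n_histogram_bins)
    for (name, var), v in histo.items():
        values[(reg.INTENSITY_HISTOGRAM, name, var)] = v

    for name, v in gauss_fit_features(volume, mask, params.n_histogram_bins).items():
        values[(reg.INTENSITY_HIST_GAUSS_FIT, name, "")] = v

    q = quantize(volume, mask, params.n_gray_levels)

    for dirs, category in ((reg.DIRECTIONS_2D, reg.GLCM2D), (reg.DIRECTIONS_3D, reg.GLCM3D)):
        for d in dirs:
            var = reg.direction_variant(d)
            m = compute_glcm(q, d, params.glcm_distance, params.glcm_symmetric)
            for name, v in glcm_features(m).items():
                values[(category, name, var)] = v

    for d in reg.DIRECTIONS_2D:
        var = reg.direction_variant(d)
        for name, v in run_length_features(q, d).items():
            values[(reg.GRAY_RUN_LENGTH_2D, name, var)] = v

    for mode, category in (("2d", reg.NID2D), ("3d", reg.NID3D)):
        for name, v in nid_features(q, mode).items():
            values[(category, name, "")] = v

    for (name, var), v in gradient_orient_features(volume, mask).items():
        values[(reg.GRADIENT_ORIENT_HISTOGRAM, name, var)] = v

    expected = set(registry.expanded_keys())
    got = set(values)
    if got != expected:
        missing = sorted(expected - got)[:5]
        extra = sorted(got - expected)[:5]
        raise FeatuniqError(
            f"extraction incomplete: missing {missing} ... / unexpected {extra} ..."
        )
    return FeatureVector(values=values, roi_id=roi_id, params=params)
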