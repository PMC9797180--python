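"""The feature registry: names, categories and variant axes of all 123 features.

Category cardinalities are fixed by construction:
IntensityDirect 34, IntensityHistogram 9, IntensityHistGaussFit 6,
GLCM2D 22, GLCM3D 22, GrayRunLength2D 11, NeighborIntensityDiff2D 5,
NeighborIntensityDiff3D 5, GradientOrientHistogram 9 — 123 in total.

Directionally dependent features carry one variant per direction;
percentile-based features one variant per decile; everything else is a
scalar (single-valued) feature.  Names follow the IBEX naming lineage;
members not fixed by an external listing are marked ``reconstructed``.
"""
from __future__ import annotations

from dataclasses import dataclass

# --- category identifiers -------------------------------------------------
INTENSITY_DIRECT = "IntensityDirect"
INTENSITY_HISTOGRAM = "IntensityHistogram"
INTENSITY_HIST_GAUSS_FIT = "IntensityHistGaussFit"
GLCM2D = "GLCM2D"
GLCM3D = "GLCM3D"
GRAY_RUN_LENGTH_2D = "GrayRunLength2D"
NID2D = "NeighborIntensityDiff2D"
NID3D = "NeighborIntensityDiff3D"
GRADIENT_ORIENT_HISTOGRAM = "GradientOrientHistogram"

CATEGORY_COUNTS: dict[str, int] = {
    INTENSITY_DIRECT: 34,
    INTENSITY_HISTOGRAM: 9,
    INTENSITY_HIST_GAUSS_FIT: 6,
    GLCM2D: 22,
    GLCM3D: 22,
    GRAY_RUN_LENGTH_2D: 11,
    NID2D: 5,
    NID3D: 5,
    GRADIENT_ORIENT_HISTOGRAM: 9,
}

#: Deciles used by percentile-based features.
DECILES: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)
DECILE_VARIANTS: tuple[str, ...] = tuple(f"p{p}" for p in DECILES)

#: In-plane offsets (dz, dy, dx) at distance 1 — Haralick's four 2D directions.
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (0, 1, 1),
    (0, 1, -1),
)

#: The 13 unique 3D directions at distance 1 (26-connectivity / 2).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def direction_variant(d: tuple[int, int, int]) -> str:
    return "d" + "".join("m" + str(-v) if v < 0 else str(v) for v in d)


DIR2D_VARIANTS = tuple(direction_variant(d) for d in DIRECTIONS_2D)
DIR3D_VARIANTS = tuple(direction_variant(d) for d in DIRECTIONS_3D)


@dataclass(frozen=True)
class FeatureDescriptor:
    category: str
    name: str
    variants: tuple[str, ...] | None = None  # None -> scalar feature
    reconstructed: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.category, self.name)

    @property
    def n_variants(self) -> int:
        return 1 if self.variants is None else len(self.variants)

    def expand(self) -> list[tuple[str, str, str]]:
        """(category, feature, variant) keys; scalar features use variant ''."""
        if self.variants is None:
            return [(self.category, self.name, "")]
        return [(self.category, self.name, v) for v in self.variants]


GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceEntropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "InformationMeasureCorr1",
    "InformationMeasureCorr2",
    "InverseDiff",
    "InverseDiffMoment",
    "InverseDiffMomentNorm",
    "InverseDiffNorm",
    "InverseVariance",
    "MaxProbability",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "Variance",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "GrayLevelNonuniformity",
    "HighGrayLevelRunEmpha",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmpha",
    "LongRunLowGrayLevelEmpha",
    "LowGrayLevelRunEmpha",
    "RunLengthNonuniformity",
    "RunPercentage",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmpha",
    "ShortRunLowGrayLevelEmpha",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)

# (name, reconstructed) — names absent from any external table listing are
# reconstructed from the IBEX lineage plus the 34-count constraint.
_INTENSITY_DIRECT: tuple[tuple[str, bool], ...] = (
    ("Energy", True),
    ("GlobalEntropy", False),
    ("GlobalMax", False),
    ("GlobalMean", True),
    ("GlobalMedian", True),
    ("GlobalMin", True),
    ("GlobalStd", False),
    ("GlobalUniformity", False),
    ("InterQuartileRange", True),
    ("Kurtosis", False),
    ("LocalEntropyMax", False),
    ("LocalEntropyMean", False),
    ("LocalEntropyMedian", False),
    ("LocalEntropyMin", False),
    ("LocalEntropyStd", False),
    ("LocalRangeMax", False),
    ("LocalRangeMean", False),
    ("LocalRangeMedian", False),
    ("LocalRangeMin", False),
    ("LocalRangeStd", False),
    ("LocalStdMax", False),
    ("LocalStdMean", False),
    ("LocalStdMedian", True),
    ("LocalStdMin", False),
    ("LocalStdStd", False),
    ("MeanAbsoluteDeviation", True),
    ("MedianAbsoluteDeviation", True),
    ("Percentile", True),
    ("PercentileArea", True),
    ("Quantile", True),
    ("Range", False),
    ("RootMeanSquare", True),
    ("Skewness", True),
    ("Variance", True),
)

_INTENSITY_HISTOGRAM: tuple[tuple[str, bool], ...] = (
    ("Entropy", True),
    ("Kurtosis", True),
    ("Mean", True),
    ("Median", True),
    ("Percentile", True),
    ("Range", False),
    ("Skewness", True),
    ("Std", True),
    ("Uniformity", True),
)

GAUSS_FIT_FEATURES: tuple[str, ...] = (
    "GaussAmplitude",
    "GaussArea",
    "GaussMean",
    "GaussStd",
    "HistArea",
    "NumberOfGauss",
)

GOH_FEATURES: tuple[str, ...] = (
    "InterQuartileRange",
    "Kurtosis",
    "MeanAbsoluteDeviation",
    "MedianAbsoluteDeviation",
    "Percentile",
    "PercentileArea",
    "Quantile",
    "Range",
    "Skewness",
)

#: Features whose variant axis is the decile grid.
PERCENTILE_BASED: frozenset[str] = frozenset({"Percentile", "PercentileArea", "Quantile"})


class FeatureRegistry:
    """Ordered collection of feature descriptors with category-count checks."""

    def __init__(self, descriptors: list[FeatureDescriptor]):
        self.descriptors = tuple(descriptors)
        keys = [d.key for d in self.descriptors]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (category, feature) in registry")
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.category] = counts.get(d.category, 0) + 1
        if counts != CATEGORY_COUNTS:
            raise ValueError(f"category counts {counts} != required {CATEGORY_COUNTS}")

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def category(self, category: str) -> list[FeatureDescriptor]:
        return [d for d in self.descriptors if d.category == category]

    def get(self, category: str, name: str) -> FeatureDescriptor:
        for d in self.descriptors:
            if d.category == category and d.name == name:
                return d
        raise KeyError((category, name))

    def keys(self) -> list[tuple[str, str]]:
        return [d.key for d in self.descriptors]

    def expanded_keys(self) -> list[tuple[str, str, str]]:
        out: list[tuple[str, str, str]] = []
        for d in self.descriptors:
            out.extend(d.expand())
        return out

    def scalar_features(self, category: str) -> list[FeatureDescriptor]:
        return [d for d in self.category(category) if d.variants is None]


def default_registry() -> FeatureRegistry:
    desc: list[FeatureDescriptor] = []
    for name, recon in _INTENSITY_DIRECT:
        variants = DECILE_VARIANTS if name in PERCENTILE_BASED else None
        desc.append(FeatureDescriptor(INTENSITY_DIRECT, name, variants, recon))
    for name, recon in _INTENSITY_HISTOGRAM:
        variants = DECILE_VARIANTS if name in PERCENTILE_BASED else None
        desc.append(FeatureDescriptor(INTENSITY_HISTOGRAM, name, variants, recon))
    for name in GAUSS_FIT_FEATURES:
        desc.append(FeatureDescriptor(INTENSITY_HIST_GAUSS_FIT, name))
    for name in GLCM_FEATURES:
        desc.append(FeatureDescriptor(GLCM2D, name, DIR2D_VARIANTS))
    for name in GLCM_FEATURES:
        desc.append(FeatureDescriptor(GLCM3D, name, DIR3D_VARIANTS))
    for name in GLRLM_FEATURES:
        desc.append(FeatureDescriptor(GRAY_RUN_LENGTH_2D, name, DIR2D_VARIANTS))
    for name in NGTDM_FEATURES:
        desc.append(FeatureDescriptor(NID2D, name))
    for name in NGTDM_FEATURES:
        desc.append(FeatureDescriptor(NID3D, name))
    for name in GOH_FEATURES:
        variants = DECILE_VARIANTS if name in PERCENTILE_BASED else None
        desc.append(FeatureDescriptor(GRADIENT_ORIENT_HISTOGRAM, name, variants))
    return FeatureRegistry(desc)
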