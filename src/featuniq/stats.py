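"""Per-patient comparison statistics across the five tissue ROIs.

For every feature, the coefficient of variation (CV, percent) is computed
across the five tissue placements of one patient, and Lin's concordance
correlation coefficient (CCC) is computed between the tumor ROI and each of
the four non-tumor ROIs (pairs T-A, T-H, T-L, T-M).

CCC grouping: a feature with two or more variants (directional or decile
based) gets its own CCC across matched variant values; scalar features
receive the category-level CCC computed across the scalar features of
their category, the same value assigned to every scalar member — so a
scalar category succeeds or fails as a block.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatuniqError
from .features.extract import FeatureVector
from .features.registry import FeatureRegistry, default_registry
from .phantom import NON_TUMOR_TISSUES

REGIONS: tuple[str, ...] = ("tumor",) + NON_TUMOR_TISSUES
TISSUE_PAIRS: tuple[str, ...] = ("T-A", "T-H", "T-L", "T-M")
_PAIR_TISSUE = dict(zip(TISSUE_PAIRS, NON_TUMOR_TISSUES))


@dataclass
class PatientFeatureTable:
    """Five FeatureVectors (one per tissue region) for one patient."""

    patient_id: str
    cohort: str
    vectors: dict[str, FeatureVector]
    registry: FeatureRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        missing = set(REGIONS) - set(self.vectors)
        if missing:
            raise FeatuniqError(f"patient {self.patient_id}: missing regions {sorted(missing)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [v.to_frame(self.patient_id, region) for region, v in self.vectors.items()],
            ignore_index=True,
        )


def coefficient_of_variation(values) -> float:
    """100 x sample std (n-1) / |mean|; NaN when degenerate.

    Undefined (NaN) inputs are dropped; fewer than two defined values, or a
    mean at zero relative to the spread, yield NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    if abs(mean) < 1e-9 * sd:
        return float("nan")
    if sd == 0.0:
        return 0.0
    return 100.0 * sd / abs(mean)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with biased (n) moments.

    2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).  Two identical constant
    series give 1; two unequal constant series give 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FeatuniqError("lin_ccc requires equal-length series")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    mx, my = x.mean(), y.mean()
    vx = float(((x - mx) ** 2).mean())
    vy = float(((y - my) ** 2).mean())
    cov = float(((x - mx) * (y - my)).mean())
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # identical constant series
    return 2.0 * cov / denom


def patient_table_from_frame(
    df: pd.DataFrame, registry: FeatureRegistry | None = None
) -> PatientFeatureTable:
    """Rebuild a PatientFeatureTable from a long-format feature CSV frame."""
    registry = registry or default_registry()
    patients = df["patient"].unique()
    if len(patients) != 1:
        raise FeatuniqError(f"expected one patient per table, got {list(patients)}")
    vectors: dict[str, FeatureVector] = {}
    df = df.copy()
    df["variant"] = df["variant"].fillna("")
    for region, grp in df.groupby("tissue_region"):
        values = {
            (r.category, r.feature, r.variant): float(r.value) for r in grp.itertuples()
        }
        vectors[region] = FeatureVector(values=values, roi_id=f"{patients[0]}:{region}")
    return PatientFeatureTable(patient_id=str(patients[0]), cohort="", vectors=vectors)


def cv_table(table: PatientFeatureTable) -> pd.Series:
    """Per-feature CV across the five regions, indexed by (category, feature).

    Multi-variant features are summarised per region by their variant mean
    before the CV is taken.
    """
    rows = {}
    for desc in table.registry:
        vals = [table.vectors[r].feature_mean(desc.category, desc.name) for r in REGIONS]
        rows[desc.key] = coefficient_of_variation(vals)
    s = pd.Series(rows, name=table.patient_id)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["category", "feature"])
    return s


def ccc_table(table: PatientFeatureTable, mode: str = "grouped") -> pd.DataFrame:
    """Per-feature, per-pair CCC; columns are the four tumor/tissue pairs.

    mode='grouped' (default): per-variant CCC for multi-variant features,
    category-level CCC shared by the scalar features of each category.
    mode='category': category-level CCC for every feature, multi-variant
    features entering through their variant means.
    """
    if mode not in ("grouped", "category"):
        raise FeatuniqError(f"unknown CCC mode {mode!r}")
    reg = table.registry
    tumor = table.vectors["tumor"]
    out: dict[str, dict[tuple[str, str], float]] = {}
    for pair in TISSUE_PAIRS:
        other = table.vectors[_PAIR_TISSUE[pair]]
        col: dict[tuple[str, str], float] = {}
        categories = sorted({d.category for d in reg})
        for category in categories:
            descs = reg.category(category)
            if mode == "grouped":
                multi = [d for d in descs if d.variants is not None]
                scal = [d for d in descs if d.variants is None]
            else:
                multi, scal = [], descs
            for d in multi:
                tv = tumor.variant_values(d.category, d.name)
                ov = other.variant_values(d.category, d.name)
                keys = sorted(tv)
                col[d.key] = lin_ccc([tv[k] for k in keys], [ov[k] for k in keys])
            if scal:
                tvals = [tumor.feature_mean(d.category, d.name) for d in scal]
                ovals = [other.feature_mean(d.category, d.name) for d in scal]
                c = lin_ccc(tvals, ovals)
                for d in scal:
                    col[d.key] = c
        out[pair] = col
    df = pd.DataFrame(out)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["category", "feature"])
    # Keep registry order.
    df = df.loc[[d.key for d in reg]]
    return df


def cohort_cv_matrix(tables: list[PatientFeatureTable]) -> pd.DataFrame:
    """Features x patients CV matrix (the layout of the CV heatmap)."""
    return pd.concat([cv_table(t) for t in tables], axis=1)


def cohort_ccc_panel(tables: list[PatientFeatureTable], mode: str = "grouped") -> pd.DataFrame:
    """Features x (pair, patient) CCC matrix (the layout of the CCC heatmap)."""
    frames = []
    for t in tables:
        df = ccc_table(t, mode=mode)
        df.columns = pd.MultiIndex.from_product([df.columns, [t.patient_id]], names=["pair", "patient"])
        frames.append(df)
    panel = pd.concat(frames, axis=1)
    return panel.sort_index(axis=1, level=["pair", "patient"])
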