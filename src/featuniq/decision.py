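"""Threshold-and-aggregation rules that classify features as unique or not.

A feature is CV-nonunique in a cohort when its CV falls below the CV
threshold (default 10%) for at least half of the patients.  A feature is
CCC-nonunique when, for two or more of the four tumor/tissue pairs, its CCC
exceeds the CCC threshold (default 0.85) for at least half of the patients.
A feature is nonunique overall when it is CV-nonunique in every cohort and
CCC-nonunique in every cohort.

The patient-fraction comparison is inclusive (count >= fraction * n) by
default; the strict variant (count > fraction * n) is available through
:class:`DecisionConfig`.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd

from .core import FeatuniqError

FeatureKey = tuple[str, str]  # (category, feature)


@dataclass(frozen=True)
class DecisionConfig:
    cv_threshold: float = 10.0  # percent
    ccc_threshold: float = 0.85
    patient_fraction: float = 0.5
    inclusive_fraction: bool = True  # count >= fraction*n (vs strict >)
    min_failing_pairs: int = 2
    exclude_hist_area: bool = False  # drop the same-shape HistArea artifact

    def __post_init__(self) -> None:
        if not (self.cv_threshold > 0):
            raise FeatuniqError("cv_threshold must be positive")
        if not (-1.0 < self.ccc_threshold < 1.0):
            raise FeatuniqError("ccc_threshold must lie in (-1, 1)")
        if not (0.0 < self.patient_fraction <= 1.0):
            raise FeatuniqError("patient_fraction must lie in (0, 1]")
        if not (1 <= self.min_failing_pairs <= 4):
            raise FeatuniqError("min_failing_pairs must lie in 1..4")

    def meets_fraction(self, count: int, n: int) -> bool:
        cut = self.patient_fraction * n
        return count >= cut if self.inclusive_fraction else count > cut


@dataclass
class CvVerdicts:
    """Per-feature CV failure counts and nonuniqueness verdicts for one cohort."""

    cohort: str
    n_patients: int
    fail_counts: dict[FeatureKey, int]
    nonunique: set[FeatureKey]


@dataclass
class CccVerdicts:
    """Per-feature CCC pair-failure structure and verdicts for one cohort."""

    cohort: str
    n_patients: int
    pair_fail_counts: dict[FeatureKey, dict[str, int]]  # patients over threshold
    pairs_failed: dict[FeatureKey, int]
    nonunique: set[FeatureKey]


def cv_verdicts_from_counts(
    counts: dict[FeatureKey, int], n_patients: int, config: DecisionConfig, cohort: str = ""
) -> CvVerdicts:
    """Decision from per-feature counts of patients with CV below threshold."""
    if n_patients < 1:
        raise FeatuniqError("cohort must contain at least one patient")
    bad = {k for k, c in counts.items() if config.meets_fraction(c, n_patients)}
    if config.exclude_hist_area:
        bad = {k for k in bad if k[1] != "HistArea"}
    return CvVerdicts(cohort, n_patients, dict(counts), bad)


def cv_verdicts(cv_matrix: pd.DataFrame, config: DecisionConfig, cohort: str = "") -> CvVerdicts:
    """Decision from a features x patients CV matrix (NaNs never fail)."""
    below = cv_matrix < config.cv_threshold  # NaN compares False
    counts = {tuple(k): int(c) for k, c in below.sum(axis=1).items()}
    return cv_verdicts_from_counts(counts, cv_matrix.shape[1], config, cohort)


def ccc_verdicts(ccc_panel: pd.DataFrame, config: DecisionConfig, cohort: str = "") -> CccVerdicts:
    """Decision from a features x (pair, patient) CCC panel."""
    above = ccc_panel > config.ccc_threshold
    per_pair = above.T.groupby(level="pair").sum().T  # features x pairs, patient counts
    n_patients = len(ccc_panel.columns.get_level_values("patient").unique())
    pair_counts = {
        tuple(k): {pair: int(row[pair]) for pair in per_pair.columns}
        for k, row in per_pair.iterrows()
    }
    pairs_failed = {
        k: sum(config.meets_fraction(c, n_patients) for c in d.values())
        for k, d in pair_counts.items()
    }
    bad = {k for k, nf in pairs_failed.items() if nf >= config.min_failing_pairs}
    return CccVerdicts(cohort, n_patients, pair_counts, pairs_failed, bad)


def ccc_verdicts_from_pair_failures(
    pairs_failed: dict[FeatureKey, int], n_patients: int, config: DecisionConfig, cohort: str = ""
) -> CccVerdicts:
    """Decision entered at the pairs-failed level (e.g. replayed table counts)."""
    bad = {k for k, nf in pairs_failed.items() if nf >= config.min_failing_pairs}
    return CccVerdicts(cohort, n_patients, {}, dict(pairs_failed), bad)


@dataclass
class UniquenessReport:
    """Combined verdicts over all cohorts, plus every intermediate set."""

    config: DecisionConfig
    registry_keys: list[FeatureKey]
    cv: dict[str, CvVerdicts]  # cohort -> verdicts
    ccc: dict[str, CccVerdicts]
    cv_all_cohorts: set[FeatureKey] = field(init=False)
    ccc_all_cohorts: set[FeatureKey] = field(init=False)
    nonunique: set[FeatureKey] = field(init=False)

    def __post_init__(self) -> None:
        cohorts = list(self.cv)
        if set(self.ccc) != set(cohorts):
            raise FeatuniqError("CV and CCC verdicts cover different cohorts")
        self.cv_all_cohorts = set.intersection(*(self.cv[c].nonunique for c in cohorts))
        self.ccc_all_cohorts = set.intersection(*(self.ccc[c].nonunique for c in cohorts))
        self.nonunique = self.cv_all_cohorts & self.ccc_all_cohorts

    @property
    def n_features(self) -> int:
        return len(self.registry_keys)

    def percent(self, count: int) -> float:
        """Share of the feature bank, rounded to the printed precision."""
        return round(100.0 * count / self.n_features, 1)

    def summary(self) -> dict:
        out: dict = {"n_features": self.n_features, "config": asdict(self.config)}
        for cohort in self.cv:
            out[f"cv_nonunique_{cohort}"] = len(self.cv[cohort].nonunique)
            out[f"cv_pct_{cohort}"] = self.percent(len(self.cv[cohort].nonunique))
            out[f"ccc_nonunique_{cohort}"] = len(self.ccc[cohort].nonunique)
            out[f"ccc_pct_{cohort}"] = self.percent(len(self.ccc[cohort].nonunique))
        out["ccc_overlap"] = len(self.ccc_all_cohorts)
        out["combined_nonunique"] = len(self.nonunique)
        out["combined_pct"] = self.percent(len(self.nonunique))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.registry_keys:
            row: dict = {"category": key[0], "feature": key[1]}
            for cohort in self.cv:
                row[f"cv_fail_{cohort}"] = self.cv[cohort].fail_counts.get(key, 0)
                row[f"cv_nonunique_{cohort}"] = key in self.cv[cohort].nonunique
                row[f"ccc_pairs_failed_{cohort}"] = self.ccc[cohort].pairs_failed.get(key, 0)
                row[f"ccc_nonunique_{cohort}"] = key in self.ccc[cohort].nonunique
            row["nonunique"] = key in self.nonunique
            rows.append(row)
        return pd.DataFrame(rows)


def combine(
    cv_by_cohort: dict[str, CvVerdicts],
    ccc_by_cohort: dict[str, CccVerdicts],
    registry_keys: list[FeatureKey],
    config: DecisionConfig,
) -> UniquenessReport:
    keyset = set(registry_keys)
    for v in list(cv_by_cohort.values()):
        extra = set(v.fail_counts) - keyset
        if extra:
            raise FeatuniqError(f"CV verdicts reference unknown features {sorted(extra)[:3]}")
    for v in list(ccc_by_cohort.values()):
        extra = set(v.pairs_failed) - keyset
        if extra:
            raise FeatuniqError(f"CCC verdicts reference unknown features {sorted(extra)[:3]}")
    return UniquenessReport(config=config, registry_keys=list(registry_keys),
                            cv=dict(cv_by_cohort), ccc=dict(ccc_by_cohort))
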