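"""Replay of the published per-feature failure counts through the decision engine.

The packaged CSVs hold, for two NSCLC cohorts (GE, n = 14 patients;
Siemens, n = 18), the number of patients in which each feature's CV fell
below 10% and the number of tumor/tissue pairs in which each feature's
CCC exceeded 0.85 for at least half the patients.  Feeding these counts
through the configured rules recomputes every headline quantity of the
screening: the per-cohort CV and CCC nonunique sets, their sizes and
percentages, the cross-cohort CCC overlap, and the combined nonunique set.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .decision import (
    CccVerdicts,
    CvVerdicts,
    DecisionConfig,
    FeatureKey,
    UniquenessReport,
    ccc_verdicts_from_pair_failures,
    combine,
    cv_verdicts_from_counts,
)
from .features.registry import default_registry

COHORTS = ("GE", "Siemens")


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("featuniq.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_cv_counts() -> pd.DataFrame:
    return _load_csv("table1_cv_counts.csv")


def load_ccc_region_failures() -> pd.DataFrame:
    return _load_csv("table2_ccc_regions_failed.csv")


def replay_cv_verdicts(config: DecisionConfig | None = None) -> dict[str, CvVerdicts]:
    config = config or DecisionConfig()
    df = load_cv_counts()
    out: dict[str, CvVerdicts] = {}
    for cohort, grp in df.groupby("cohort"):
        n = int(grp["n_patients"].iloc[0])
        counts: dict[FeatureKey, int] = {
            (r.category, r.feature): int(r.patients_failed) for r in grp.itertuples()
        }
        out[cohort] = cv_verdicts_from_counts(counts, n, config, cohort)
    return out


def replay_ccc_verdicts(config: DecisionConfig | None = None) -> dict[str, CccVerdicts]:
    config = config or DecisionConfig()
    df = load_ccc_region_failures()
    out: dict[str, CccVerdicts] = {}
    for cohort, grp in df.groupby("cohort"):
        n = int(grp["n_patients"].iloc[0])
        pairs_failed: dict[FeatureKey, int] = {
            (r.category, r.feature): int(r.regions_failed) for r in grp.itertuples()
        }
        out[cohort] = ccc_verdicts_from_pair_failures(pairs_failed, n, config, cohort)
    return out


def replay_report(config: DecisionConfig | None = None) -> UniquenessReport:
    """Run the full decision replay and return the combined report."""
    config = config or DecisionConfig()
    registry = default_registry()
    cv = replay_cv_verdicts(config)
    ccc = replay_ccc_verdicts(config)
    return combine(cv, ccc, registry.keys(), config)
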