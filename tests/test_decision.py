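import numpy as np
import pandas as pd
import pytest

from featuniq.core import FeatuniqError
from featuniq.decision import (
    DecisionConfig,
    ccc_verdicts,
    ccc_verdicts_from_pair_failures,
    combine,
    cv_verdicts,
    cv_verdicts_from_counts,
)
from featuniq.features.registry import default_registry
from featuniq.tables import (
    load_ccc_region_failures,
    load_cv_counts,
    replay_ccc_verdicts,
    replay_cv_verdicts,
    replay_report,
)

REG = default_registry()


class TestConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(FeatuniqError):
            DecisionConfig(cv_threshold=0.0)
        with pytest.raises(FeatuniqError):
            DecisionConfig(ccc_threshold=1.5)
        with pytest.raises(FeatuniqError):
            DecisionConfig(patient_fraction=0.0)
        with pytest.raises(FeatuniqError):
            DecisionConfig(min_failing_pairs=5)

    def test_inclusive_vs_strict_fraction(self):
        c_in = DecisionConfig(inclusive_fraction=True)
        c_st = DecisionConfig(inclusive_fraction=False)
        assert c_in.meets_fraction(9, 18)
        assert not c_st.meets_fraction(9, 18)
        assert c_st.meets_fraction(10, 18)


class TestCvVerdicts:
    def test_counts_at_half_qualify_inclusively(self):
        counts = {("C", "a"): 7, ("C", "b"): 6}
        v = cv_verdicts_from_counts(counts, 14, DecisionConfig())
        assert v.nonunique == {("C", "a")}

    def test_all_zero_counts_no_feature_flagged(self):
        counts = {k: 0 for k in REG.keys()}
        v = cv_verdicts_from_counts(counts, 14, DecisionConfig())
        assert v.nonunique == set()

    def test_matrix_path_ignores_nans(self):
        m = pd.DataFrame(
            {"p0": [5.0, np.nan], "p1": [5.0, np.nan]},
            index=pd.MultiIndex.from_tuples([("C", "a"), ("C", "b")]),
        )
        v = cv_verdicts(m, DecisionConfig())
        assert v.nonunique == {("C", "a")}
        assert v.fail_counts[("C", "b")] == 0


class TestCccVerdicts:
    def test_single_failing_pair_stays_unique(self):
        v = ccc_verdicts_from_pair_failures({("C", "a"): 1, ("C", "b"): 2}, 10, DecisionConfig())
        assert v.nonunique == {("C", "b")}

    def test_panel_path_counts_patients_per_pair(self):
        cols = pd.MultiIndex.from_product(
            [["T-A", "T-H", "T-L", "T-M"], ["p0", "p1"]], names=["pair", "patient"]
        )
        # feature a: CCC 0.9 everywhere -> 4 pairs fail; feature b: low CCC.
        data = np.vstack([np.full(8, 0.9), np.full(8, 0.1)])
        panel = pd.DataFrame(data, index=pd.MultiIndex.from_tuples([("C", "a"), ("C", "b")]), columns=cols)
        v = ccc_verdicts(panel, DecisionConfig())
        assert v.nonunique == {("C", "a")}
        assert v.pairs_failed[("C", "a")] == 4
        assert v.pairs_failed[("C", "b")] == 0


class TestReplay:
    def test_ge_cv_set_has_twelve_features(self):
        v = replay_cv_verdicts()["GE"]
        assert len(v.nonunique) == 12

    def test_siemens_cv_needs_inclusive_rule_for_29(self):
        assert len(replay_cv_verdicts()["Siemens"].nonunique) == 29
        strict = replay_cv_verdicts(DecisionConfig(inclusive_fraction=False))
        assert len(strict["Siemens"].nonunique) == 26  # 9/18 entries drop out

    def test_ccc_sets_18_and_16(self):
        v = replay_ccc_verdicts()
        assert len(v["GE"].nonunique) == 18
        assert len(v["Siemens"].nonunique) == 16

    def test_cross_cohort_ccc_overlap_is_eleven(self):
        r = replay_report()
        assert len(r.ccc_all_cohorts) == 11

    def test_combined_set_size_and_membership(self):
        r = replay_report()
        assert len(r.nonunique) == 9
        goh = {f for c, f in r.nonunique if c == "GradientOrientHistogram"}
        assert goh == {
            "InterQuartileRange",
            "Kurtosis",
            "MeanAbsoluteDeviation",
            "MedianAbsoluteDeviation",
            "Percentile",
            "PercentileArea",
            "Range",
        }
        assert {("GLCM3D", "InverseDiffMomentNorm"), ("GLCM3D", "InverseDiffNorm")} <= r.nonunique

    def test_fixture_features_all_in_registry(self):
        keys = set(REG.keys())
        for df in (load_cv_counts(), load_ccc_region_failures()):
            fixture_keys = {(r.category, r.feature) for r in df.itertuples()}
            assert fixture_keys <= keys

    def test_hist_area_exclusion_flag(self):
        r = replay_report(DecisionConfig(exclude_hist_area=True))
        assert ("IntensityHistGaussFit", "HistArea") not in r.cv["GE"].nonunique
        assert len(r.cv["GE"].nonunique) == 11


class TestCombine:
    def test_overall_set_is_intersection(self):
        r = replay_report()
        for cohort in ("GE", "Siemens"):
            assert r.nonunique <= r.cv[cohort].nonunique
            assert r.nonunique <= r.ccc[cohort].nonunique

    def test_single_cohort_degeneracy(self):
        cv = {"GE": replay_cv_verdicts()["GE"]}
        ccc = {"GE": replay_ccc_verdicts()["GE"]}
        r = combine(cv, ccc, REG.keys(), DecisionConfig())
        assert r.nonunique == cv["GE"].nonunique & ccc["GE"].nonunique

    def test_unknown_feature_rejected(self):
        v = cv_verdicts_from_counts({("Bogus", "x"): 10}, 14, DecisionConfig())
        with pytest.raises(FeatuniqError, match="unknown"):
            combine({"GE": v}, {"GE": replay_ccc_verdicts()["GE"]}, REG.keys(), DecisionConfig())

    def test_cohort_mismatch_rejected(self):
        with pytest.raises(FeatuniqError):
            combine(
                {"GE": replay_cv_verdicts()["GE"]},
                {"Siemens": replay_ccc_verdicts()["Siemens"]},
                REG.keys(),
                DecisionConfig(),
            )


class TestMonotonicity:
    @pytest.mark.parametrize("field,low,high", [
        ("ccc_threshold", 0.85, 0.95),
        ("patient_fraction", 0.5, 0.7),
    ])
    def test_raising_thresholds_never_enlarges_sets(self, field, low, high):
        r_low = replay_report(DecisionConfig(**{field: low}))
        r_high = replay_report(DecisionConfig(**{field: high}))
        for cohort in ("GE", "Siemens"):
            assert r_high.ccc[cohort].nonunique <= r_low.ccc[cohort].nonunique
            if field == "patient_fraction":
                assert r_high.cv[cohort].nonunique <= r_low.cv[cohort].nonunique
        assert r_high.nonunique <= r_low.nonunique

    def test_lowering_cv_threshold_never_enlarges_cv_set(self):
        # Replayed counts are tied to the 10% threshold; exercise the rule on
        # a synthetic matrix instead.
        m = pd.DataFrame(
            {"p0": [4.0, 8.0], "p1": [6.0, 12.0]},
            index=pd.MultiIndex.from_tuples([("C", "a"), ("C", "b")]),
        )
        wide = cv_verdicts(m, DecisionConfig(cv_threshold=10.0))
        narrow = cv_verdicts(m, DecisionConfig(cv_threshold=5.0))
        assert narrow.nonunique <= wide.nonunique

    def test_report_summary_percentages(self):
        r = replay_report()
        s = r.summary()
        assert s["cv_pct_GE"] == 9.8
        assert s["combined_pct"] == 7.3
        assert r.to_frame().shape[0] == 123
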