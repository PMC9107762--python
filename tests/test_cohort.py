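import io

import numpy as np
import pandas as pd
import pytest

from sca3prog import (
    CohortConfig,
    CohortLoadError,
    Sca3ProgError,
    compute_duration,
    compute_rao,
    generate_cohort,
    read_cohort,
    remove_duration_outliers,
    summarize_cohort,
    write_cohort,
)
from sca3prog.cohort import validate_cohort


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


HEADER = "subject_id,cag_exp,aoga,gender,age_at_exam,duration,icars"


class TestReadWrite:
    def test_three_row_fixture(self):
        cohort = read_cohort(_csv(f"""
{HEADER}
P1,67,40.0,female,45.0,,12.0
P1,67,40.0,female,46.5,,15.0
P1,67,40.0,female,48.0,,19.5
"""))
        assert cohort.subject_id.nunique() == 1
        assert len(cohort) == 3
        np.testing.assert_allclose(cohort.duration, [5.0, 6.5, 8.0])

    def test_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        again = read_cohort(path)
        assert len(again) == len(small_cohort)
        for col in ("duration", "icars", "aoga"):
            np.testing.assert_allclose(
                again[col], small_cohort.sort_values(
                    ["subject_id", "duration"])[col], atol=1e-6)

    def test_inconsistent_gender_names_subject(self):
        with pytest.raises(CohortLoadError, match="P1"):
            read_cohort(_csv(f"""
{HEADER}
P1,67,40.0,female,45.0,,12.0
P1,67,40.0,male,46.0,,14.0
"""))

    def test_non_numeric_field_rejected(self):
        with pytest.raises(CohortLoadError, match="icars"):
            read_cohort(_csv(f"""
{HEADER}
P1,67,40.0,female,45.0,,twelve
"""))

    def test_missing_icars_row_dropped_with_report(self, caplog):
        with caplog.at_level("WARNING", logger="sca3prog.cohort"):
            cohort = read_cohort(_csv(f"""
{HEADER}
P1,67,40.0,female,45.0,,12.0
P1,67,40.0,female,46.0,,
"""))
        assert len(cohort) == 1
        assert any("missing icars" in r.message for r in caplog.records)

    def test_inconsistent_duration_rejected(self):
        with pytest.raises(CohortLoadError, match="inconsistent"):
            read_cohort(_csv(f"""
{HEADER}
P1,67,40.0,female,45.0,3.0,12.0
"""))

    def test_out_of_range_icars_strict(self):
        text = f"""
{HEADER}
P1,67,40.0,female,45.0,,120.0
"""
        assert len(read_cohort(_csv(text))) == 1  # lenient by default
        with pytest.raises(CohortLoadError):
            read_cohort(_csv(text), strict=True)


class TestComputeDuration:
    def test_table1_means_relation(self):
        assert compute_duration(49.2, 42.1) == pytest.approx(7.1)

    def test_zero_duration_row_dropped_by_validation(self):
        df = pd.DataFrame({
            "subject_id": ["A"], "cag_exp": [67], "aoga": [42.1],
            "gender": ["male"], "age_at_exam": [42.1],
            "duration": [np.nan], "icars": [5.0],
        })
        assert len(validate_cohort(df)) == 0

    def test_pre_onset_rejected(self):
        with pytest.raises(Sca3ProgError):
            compute_duration(40.0, 42.1)


def _outlier_fixture():
    """81 in-range subjects plus one with 8 visits reaching 41 years."""
    cohort = generate_cohort(CohortConfig(n_subjects=85, seed=21))
    cohort, _ = remove_duration_outliers(cohort, 40.0)  # ensure base in range
    keep = cohort.subject_id.unique()[:81]
    cohort = cohort[cohort.subject_id.isin(keep)].reset_index(drop=True)
    extra = pd.DataFrame({
        "subject_id": ["OUT"] * 8, "cag_exp": [65] * 8, "aoga": [30.0] * 8,
        "gender": ["male"] * 8,
        "duration": np.linspace(34.0, 41.0, 8),
        "icars": np.linspace(60, 90, 8),
    })
    extra["age_at_exam"] = extra.aoga + extra.duration
    return pd.concat([cohort, extra], ignore_index=True)


class TestOutlierFilter:
    def test_removes_whole_subject(self):
        cohort = _outlier_fixture()
        filtered, report = remove_duration_outliers(cohort, 40.0)
        assert filtered.subject_id.nunique() == 81
        assert report["n_rows_removed"] == 8
        assert report["removed_subjects"] == {"OUT": 8}
        assert len(filtered) == len(cohort) - 8

    def test_idempotent(self):
        filtered, _ = remove_duration_outliers(_outlier_fixture(), 40.0)
        again, report = remove_duration_outliers(filtered, 40.0)
        pd.testing.assert_frame_equal(again, filtered)
        assert report["n_rows_removed"] == 0

    def test_infinite_threshold_is_identity(self):
        cohort = _outlier_fixture()
        filtered, _ = remove_duration_outliers(cohort, np.inf)
        pd.testing.assert_frame_equal(filtered, cohort)

    def test_all_subjects_exceed(self):
        cohort = _outlier_fixture()
        filtered, report = remove_duration_outliers(cohort, 0.0)
        assert len(filtered) == 0
        assert report["n_subjects_removed"] == cohort.subject_id.nunique()


class TestRao:
    def test_exactly_linear_onset_gives_zero_rao(self):
        df = pd.DataFrame({
            "subject_id": list("ABCD"), "cag_exp": [60, 65, 70, 75],
            "aoga": [60.0, 50.0, 40.0, 30.0], "gender": ["male"] * 4,
            "duration": [1.0] * 4, "icars": [5.0] * 4,
        })
        res = compute_rao(df)
        np.testing.assert_allclose(res.per_subject.rao, 0.0, atol=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_residual_mean_zero(self, pm1_cohort):
        res = compute_rao(pm1_cohort)
        assert abs(res.per_subject.rao.mean()) < 1e-9

    def test_recovers_configured_r2(self):
        cohort = generate_cohort(CohortConfig(n_subjects=10_000, seed=22))
        assert compute_rao(cohort).r_squared == pytest.approx(0.49, abs=0.02)

    def test_degenerate_cag_rejected(self):
        df = pd.DataFrame({
            "subject_id": list("ABC"), "cag_exp": [67] * 3,
            "aoga": [40.0, 45.0, 50.0], "gender": ["male"] * 3,
            "duration": [1.0] * 3, "icars": [5.0] * 3,
        })
        with pytest.raises(Sca3ProgError):
            compute_rao(df)


class TestSummary:
    def test_single_subject_two_visits(self):
        df = pd.DataFrame({
            "subject_id": ["A", "A"], "cag_exp": [67, 67],
            "aoga": [40.0, 40.0], "gender": ["female", "female"],
            "duration": [2.0, 3.5], "icars": [10.0, 12.0],
        })
        s = summarize_cohort(df)
        assert s.n_exams == 2
        assert s.followup_years.mean == pytest.approx(1.5)
        assert s.interval_years.mean == pytest.approx(1.5)
        assert s.icars_first.mean == pytest.approx(10.0)

    def test_two_subject_fixture_by_hand(self):
        df = pd.DataFrame({
            "subject_id": ["A", "A", "A", "B"],
            "cag_exp": [62, 62, 62, 70],
            "aoga": [50.0, 50.0, 50.0, 36.0],
            "gender": ["female", "female", "female", "male"],
            "duration": [1.0, 2.0, 4.0, 6.0],
            "icars": [8.0, 11.0, 20.0, 30.0],
        })
        s = summarize_cohort(df)
        assert s.n_subjects == 2 and s.n_female == 1 and s.n_exams == 4
        # per-subject visit counts 3 and 1
        assert s.visits_per_subject.mean == pytest.approx(2.0)
        assert s.visits_per_subject.sd == pytest.approx(np.std([3, 1], ddof=1))
        # follow-up spans 3.0 and 0.0; only A contributes an interval (mean 1.5)
        assert s.followup_years.mean == pytest.approx(1.5)
        assert s.interval_years.mean == pytest.approx(1.5)
        assert s.cag_exp.mean == pytest.approx(66.0)
        assert s.duration_first.mean == pytest.approx(3.5)

    def test_generated_cohort_matches_targets(self):
        cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=23))
        s = summarize_cohort(cohort)
        assert s.visits_per_subject.mean == pytest.approx(7.83, abs=0.3)
        assert s.cag_exp.mean == pytest.approx(67.7, abs=0.3)
        assert s.aoga.mean == pytest.approx(42.1, abs=0.7)
        assert s.duration_first.mean == pytest.approx(7.11, abs=0.4)
        assert s.interval_years.mean == pytest.approx(1.21, abs=0.1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(Sca3ProgError):
            summarize_cohort(pd.DataFrame(columns=["subject_id", "duration",
                                                   "icars"]))
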