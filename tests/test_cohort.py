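"""Cohort assembly: glycemia classification, time zero, exclusion flow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lctraj.cohort import (
    apply_exclusions,
    assign_time_zero,
    classify_glycemia,
    compute_backward_time,
)
from lctraj.simulate import generate_flow_cohort


class TestClassifyGlycemia:
    @pytest.mark.parametrize(
        "fpg, pg2h, fasting, expected",
        [
            (7.0, None, 10, "diabetes"),  # at-threshold fasting glucose
            (6.9, 11.0, 10, "no_diabetes"),  # both just below threshold
            (5.2, 5.2, 9, "no_diabetes"),  # typical diabetes-free values
            (7.5, None, 6, "indeterminate"),  # < 8 h fast invalidates the OGTT
            (None, 11.1, None, "diabetes"),  # 2-hour value alone suffices
            (None, None, 10, "indeterminate"),  # no glucose values at all
            (6.0, None, None, "no_diabetes"),  # missing fast treated as valid
        ],
    )
    def test_rule_table(self, fpg, pg2h, fasting, expected):
        assert classify_glycemia(fpg, pg2h, fasting) == expected

    def test_negative_glucose_rejected(self):
        with pytest.raises(ValueError):
            classify_glycemia(-1.0, None, 10)

    @given(
        fpg=st.floats(0, 15),
        pg2h=st.floats(0, 25),
        bump=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_glucose(self, fpg, pg2h, bump):
        before = classify_glycemia(fpg, pg2h, 10)
        after = classify_glycemia(fpg + bump, pg2h + bump, 10)
        if before == "diabetes":
            assert after == "diabetes"


class TestTimeZero:
    def _records(self, rows):
        df = pd.DataFrame(rows)
        for col in ("exam_date", "self_report_diabetes_date"):
            if col in df:
                df[col] = pd.to_datetime(df[col])
        return df

    def test_screen_route_uses_diagnosing_ogtt(self):
        recs = self._records(
            [
                {"exam_date": "1997-06-01", "fpg": 5.0, "pg2h": 5.0, "phase": 5},
                {"exam_date": "2002-06-15", "fpg": 7.4, "pg2h": 12.0, "phase": 7},
            ]
        )
        assert assign_time_zero(recs, "incident", "screen") == pd.Timestamp(
            "2002-06-15"
        )

    def test_doctor_route_uses_midpoint(self):
        recs = self._records(
            [
                {
                    "exam_date": "2002-01-01",
                    "fpg": 5.0,
                    "pg2h": 5.0,
                    "phase": 7,
                    "self_report_diabetes_date": pd.NaT,
                },
                {
                    "exam_date": "2004-06-01",
                    "fpg": np.nan,
                    "pg2h": np.nan,
                    "phase": 9,
                    "self_report_diabetes_date": "2004-01-01",
                },
            ]
        )
        assert assign_time_zero(recs, "incident", "doctor") == pd.Timestamp(
            "2003-01-01"
        )

    def test_diabetes_free_uses_last_exam(self):
        recs = self._records(
            [
                {"exam_date": "1992-01-01", "phase": 3, "fpg": 5.0, "pg2h": 5.0},
                {"exam_date": "1997-01-01", "phase": 5, "fpg": 5.0, "pg2h": 5.0},
                {"exam_date": "2008-03-15", "phase": 9, "fpg": 5.0, "pg2h": 5.0},
            ]
        )
        assert assign_time_zero(recs, "diabetes-free", "none") == pd.Timestamp(
            "2008-03-15"
        )

    def test_inconsistent_chronology_raises(self):
        recs = self._records(
            [
                {
                    "exam_date": "2004-06-01",
                    "fpg": 5.0,
                    "pg2h": 5.0,
                    "phase": 9,
                    "self_report_diabetes_date": "2002-01-01",
                }
            ]
        )
        with pytest.raises(ValueError, match="chronolog"):
            assign_time_zero(recs, "incident", "doctor")


class TestBackwardTime:
    @pytest.mark.parametrize("years", [5.0, 0.0, 18.0])
    def test_round_trip(self, years):
        tz = pd.Timestamp("2008-06-30")
        exam = tz - pd.Timedelta(days=round(years * 365.25))
        assert compute_backward_time(exam, tz) == pytest.approx(-years, abs=2e-3)


class TestExclusionFlow:
    def test_printed_counts_reproduced(self):
        raw = generate_flow_cohort(seed=0)
        dataset, flow = apply_exclusions(raw)
        remaining = [r for _, _, r in flow.steps]
        assert remaining == [8351, 8140, 7364, 6705]
        assert flow.n_final == dataset.n_subjects == 6705

    def test_flow_telescopes_and_retained_subjects_valid(self):
        raw = generate_flow_cohort(
            n_total=400,
            n_lost=30,
            n_prevalent=10,
            n_unassessable=25,
            n_no_bmi=15,
            n_incident=40,
            seed=3,
        )
        dataset, flow = apply_exclusions(raw)
        n = flow.n_initial
        for _, excluded, remaining in flow.steps:
            assert remaining == n - excluded
            n = remaining
        assert n == dataset.n_subjects
        assert (dataset.records["t"] <= 0).all()
        has_bmi = dataset.records.groupby("subject_id")["bmi"].apply(
            lambda s: s.notna().any()
        )
        assert has_bmi.all()

    def test_overlapping_violations_counted_once(self):
        raw = generate_flow_cohort(
            n_total=200,
            n_lost=10,
            n_prevalent=20,
            n_unassessable=15,
            n_no_bmi=5,
            n_incident=10,
            seed=1,
            overlap_prevalent_unassessable=8,
        )
        _, flow = apply_exclusions(raw)
        counts = {label: e for label, e, _ in flow.steps}
        assert counts["prevalent diabetes at first clinical examination"] == 20
        assert counts["diabetes status not assessable at any phase"] == 15
        assert flow.n_final == 150

    def test_empty_cohort(self):
        raw = generate_flow_cohort(
            n_total=0, n_lost=0, n_prevalent=0, n_unassessable=0,
            n_no_bmi=0, n_incident=0, seed=0,
        )
        dataset, flow = apply_exclusions(raw)
        assert flow.n_initial == 0 and flow.n_final == 0
        assert dataset.n_subjects == 0

    def test_incident_subjects_diabetes_free_at_first_exam(self):
        raw = generate_flow_cohort(
            n_total=300, n_lost=20, n_prevalent=10, n_unassessable=10,
            n_no_bmi=10, n_incident=30, seed=2,
        )
        dataset, _ = apply_exclusions(raw)
        incident = dataset.subjects[dataset.subjects["diabetes_status"] == "incident"]
        first = (
            dataset.records.sort_values("exam_date")
            .groupby("subject_id")
            .first()
            .loc[incident.index]
        )
        for _, row in first.iterrows():
            assert (
                classify_glycemia(row["fpg"], row["pg2h"], row["fasting_hours"])
                == "no_diabetes"
            )
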