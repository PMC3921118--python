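"""Cohort assembly on a backward time axis.

Builds the analysis dataset from a long-format table of clinical
examinations: OGTT-based glycemia classification (WHO 1999 thresholds),
incident/prevalent diabetes ascertainment, sequential exclusion filtering
with flow accounting, per-subject time-zero assignment (date of diagnosis,
or last examination for diabetes-free subjects), and conversion of calendar
dates to years before time zero (t <= 0).

The in-memory containers are pandas DataFrames: one row per
subject-examination for the records, one row per subject for status and
time zero.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: WHO 1999 OGTT thresholds for diabetes, mmol/l.
FPG_THRESHOLD = 7.0
PG2H_THRESHOLD = 11.1

#: Minimum documented fast for a valid OGTT, hours.
MIN_FASTING_HOURS = 8.0

#: Days per year for date -> years conversion.
DAYS_PER_YEAR = 365.25

#: Canonical record columns expected in raw input.
DATE_COLUMNS = ("exam_date", "self_report_diabetes_date")


@dataclass
class FlowReport:
    """Ordered exclusion-step accounting (the participant flow diagram).

    ``steps`` is an ordered list of (step_label, n_excluded, n_remaining);
    counts telescope so that each step's n_remaining equals the previous
    n_remaining minus its n_excluded.
    """

    n_initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, label: str, n_excluded: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_initial
        self.steps.append((label, int(n_excluded), int(prev - n_excluded)))

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "n_excluded", "n_remaining"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_initial": self.n_initial,
                "steps": [
                    {"step": s, "n_excluded": e, "n_remaining": r}
                    for s, e, r in self.steps
                ],
                "n_final": self.n_final,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class LongitudinalDataset:
    """Retained subject-examination records with per-subject status.

    ``records`` has one row per examination with backward time ``t`` in
    years (t <= 0, t = 0 at time zero).  ``subjects`` is indexed by
    subject_id with columns ``time_zero`` (calendar date),
    ``diabetes_status`` in {"incident", "diabetes-free"} and
    ``diagnosis_route`` in {"screen", "doctor", "none"}.
    """

    records: pd.DataFrame
    subjects: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def incident_subset(self) -> "LongitudinalDataset":
        """Records of subjects who developed diabetes during follow-up."""
        keep = self.subjects.index[self.subjects["diabetes_status"] == "incident"]
        return LongitudinalDataset(
            records=self.records[self.records["subject_id"].isin(keep)].copy(),
            subjects=self.subjects.loc[keep].copy(),
        )

    def to_csv(self, path: str | Path) -> None:
        merged = self.records.merge(
            self.subjects.reset_index()[
                ["subject_id", "time_zero", "diabetes_status", "diagnosis_route"]
            ],
            on="subject_id",
            how="left",
        )
        merged.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a raw long-format cohort table (CSV/TSV, ISO-8601 dates)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in DATE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def classify_glycemia(fpg: float, pg2h: float, fasting_hours: float) -> str:
    """WHO OGTT classification of one examination.

    Returns ``"diabetes"`` if fasting plasma glucose >= 7.0 mmol/l or 2-hour
    plasma glucose >= 11.1 mmol/l, ``"no_diabetes"`` if both available
    values are below threshold, and ``"indeterminate"`` if the documented
    fast was under 8 hours or both glucose values are missing.  A missing
    ``fasting_hours`` is treated as a valid (>= 8 h) fast.
    """
    fpg_ok = fpg is not None and not pd.isna(fpg)
    pg2h_ok = pg2h is not None and not pd.isna(pg2h)
    if fpg_ok and fpg < 0 or pg2h_ok and pg2h < 0:
        raise ValueError("glucose concentrations must be non-negative")
    if fasting_hours is not None and not pd.isna(fasting_hours):
        if fasting_hours < MIN_FASTING_HOURS:
            return "indeterminate"
    if not fpg_ok and not pg2h_ok:
        return "indeterminate"
    if (fpg_ok and fpg >= FPG_THRESHOLD) or (pg2h_ok and pg2h >= PG2H_THRESHOLD):
        return "diabetes"
    return "no_diabetes"


def _classify_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorised WHO classification of every examination row."""
    fpg = records["fpg"] if "fpg" in records else pd.Series(np.nan, records.index)
    pg2h = records["pg2h"] if "pg2h" in records else pd.Series(np.nan, records.index)
    if (fpg.dropna() < 0).any() or (pg2h.dropna() < 0).any():
        raise ValueError("glucose concentrations must be non-negative")
    if "fasting_hours" in records:
        short_fast = records["fasting_hours"].notna() & (
            records["fasting_hours"] < MIN_FASTING_HOURS
        )
    else:
        short_fast = pd.Series(False, records.index)
    out = pd.Series("no_diabetes", index=records.index, dtype=object)
    out[(fpg >= FPG_THRESHOLD) | (pg2h >= PG2H_THRESHOLD)] = "diabetes"
    out[short_fast | (fpg.isna() & pg2h.isna())] = "indeterminate"
    return out


def assign_time_zero(
    subject_records: pd.DataFrame, status: str, route: str
) -> pd.Timestamp:
    """Anchor date for the backward time axis of one subject.

    Screen-detected incident diabetes anchors at the date of the diagnosing
    OGTT; doctor-diagnosed cases at the calendar midpoint between the first
    self-reported diabetes date and the last diabetes-free screening; and
    diabetes-free subjects at their last examination.
    """
    recs = subject_records.sort_values("exam_date")
    if status == "diabetes-free":
        return recs["exam_date"].iloc[-1]
    if route == "screen":
        glyc = _classify_frame(recs)
        diag = recs.loc[glyc == "diabetes", "exam_date"]
        if diag.empty:
            raise ValueError("screen route requires a diagnosing OGTT")
        return diag.iloc[0]
    if route == "doctor":
        report = recs["self_report_diabetes_date"].dropna()
        if report.empty:
            raise ValueError("doctor route requires a self-report date")
        first_report = report.min()
        glyc = _classify_frame(recs)
        free = recs.loc[
            (glyc == "no_diabetes") & (recs["exam_date"] < first_report), "exam_date"
        ]
        if free.empty:
            raise ValueError(
                "inconsistent chronology: self-reported diabetes precedes "
                "every diabetes-free screening"
            )
        last_free = free.max()
        return last_free + (first_report - last_free) / 2
    raise ValueError(f"unknown diagnosis route: {route!r}")


def compute_backward_time(exam_date, time_zero) -> float | np.ndarray:
    """Years between an examination and the subject's time zero (<= 0)."""
    delta = pd.to_datetime(exam_date) - pd.to_datetime(time_zero)
    days = delta / pd.Timedelta(days=1)
    if isinstance(days, pd.Series):
        return (days / DAYS_PER_YEAR).to_numpy()
    return float(np.asarray(days) / DAYS_PER_YEAR)


# ---------------------------------------------------------------------------
# Exclusion flow


EXCLUSION_STEPS = (
    "lost to follow-up before first OGTT phase",
    "prevalent diabetes at first clinical examination",
    "diabetes status not assessable at any phase",
    "no BMI measurement throughout the study",
)


def _subject_flags(records: pd.DataFrame, first_ogtt_phase: int) -> pd.DataFrame:
    """Per-subject exclusion predicates derived from the raw records.

    Vectorised over subjects; semantics match applying the scalar rules to
    each subject's chronologically sorted in-study records.
    """
    all_ids = pd.Index(sorted(records["subject_id"].unique()), name="subject_id")
    recs = records.sort_values(["subject_id", "exam_date"]).copy()
    recs["_glyc"] = _classify_frame(recs)
    in_study = recs[recs["phase"] >= first_ogtt_phase]
    by = in_study.groupby("subject_id")

    lost = ~all_ids.isin(in_study["subject_id"])

    det = in_study[in_study["_glyc"] != "indeterminate"]
    first_det = det.groupby("subject_id").first()
    prevalent_screen = first_det["_glyc"] == "diabetes"

    if "self_report_diabetes_date" in in_study:
        first_report = by["self_report_diabetes_date"].min()
        has_doctor = first_report.notna()
    else:
        has_doctor = pd.Series(False, index=by.size().index)
        first_report = pd.Series(pd.NaT, index=by.size().index)
    first_exam = by["exam_date"].first()
    prevalent_doctor = has_doctor & (first_report <= first_exam)

    prevalent = (
        prevalent_screen.reindex(all_ids, fill_value=False)
        | prevalent_doctor.reindex(all_ids, fill_value=False)
    ) & ~lost
    assessable = (
        pd.Index(all_ids).isin(det["subject_id"])
        | has_doctor.reindex(all_ids, fill_value=False).values
    )
    if "bmi" in in_study:
        has_bmi = by["bmi"].apply(lambda s: s.notna().any())
    else:
        has_bmi = pd.Series(False, index=by.size().index)
    has_bmi = has_bmi.reindex(all_ids, fill_value=False)

    return pd.DataFrame(
        {
            "lost": lost,
            "prevalent": prevalent.values,
            "not_assessable": ~lost & ~assessable,
            "no_bmi": ~lost & ~has_bmi.values,
        },
        index=all_ids,
    )


def _ascertain_status(records: pd.DataFrame) -> pd.DataFrame:
    """Incident/diabetes-free status and diagnosis route per retained subject.

    OGTT evidence takes precedence over a doctor's diagnosis when both are
    present (screen-first rule).  Time zero follows :func:`assign_time_zero`:
    diagnosing-OGTT date (screen), midpoint of first self-report and last
    prior diabetes-free screening (doctor), last examination (diabetes-free).
    """
    recs = records.sort_values(["subject_id", "exam_date"]).copy()
    recs["_glyc"] = _classify_frame(recs)
    by = recs.groupby("subject_id")
    out = pd.DataFrame(index=by.size().index)
    out.index.name = "subject_id"

    screen_tz = (
        recs.loc[recs["_glyc"] == "diabetes"].groupby("subject_id")["exam_date"].first()
    )
    if "self_report_diabetes_date" in recs:
        first_report = by["self_report_diabetes_date"].min()
    else:
        first_report = pd.Series(pd.NaT, index=out.index)

    out["diabetes_status"] = "diabetes-free"
    out["diagnosis_route"] = "none"
    is_screen = out.index.isin(screen_tz.index)
    is_doctor = first_report.notna().values & ~is_screen
    out.loc[is_screen, ["diabetes_status", "diagnosis_route"]] = ["incident", "screen"]
    out.loc[is_doctor, ["diabetes_status", "diagnosis_route"]] = ["incident", "doctor"]

    tz = by["exam_date"].last()  # diabetes-free default: last examination
    tz.loc[screen_tz.index] = screen_tz

    doctor_ids = out.index[is_doctor]
    if len(doctor_ids) > 0:
        free = recs[recs["_glyc"] == "no_diabetes"].merge(
            first_report.rename("_report"), left_on="subject_id", right_index=True
        )
        free = free[free["exam_date"] < free["_report"]]
        last_free = free.groupby("subject_id")["exam_date"].max()
        missing = doctor_ids.difference(last_free.index)
        if len(missing) > 0:
            raise ValueError(
                "inconsistent chronology: self-reported diabetes precedes every "
                f"diabetes-free screening for subject(s) {list(missing)[:5]}"
            )
        lf = last_free.loc[doctor_ids]
        fr = first_report.loc[doctor_ids]
        tz.loc[doctor_ids] = lf + (fr - lf) / 2
    out["time_zero"] = tz
    return out


def apply_exclusions(
    raw: pd.DataFrame, first_ogtt_phase: int = 3
) -> tuple[LongitudinalDataset, FlowReport]:
    """Apply the study exclusion rules in order and assemble the dataset.

    Rules, applied sequentially with each subject counted only at the first
    rule it violates: (1) lost to follow-up before the first OGTT phase,
    (2) prevalent diabetes at the first clinical examination, (3) diabetes
    status not assessable at any phase, (4) no BMI measurement.  Retained
    subjects get a time zero, backward time ``t`` per record, and incident /
    diabetes-free status; records after time zero are dropped with a logged
    warning.
    """
    all_ids = pd.Index(sorted(raw["subject_id"].unique()), name="subject_id")
    flow = FlowReport(n_initial=len(all_ids))
    if len(all_ids) == 0:
        for label in EXCLUSION_STEPS:
            flow.add(label, 0)
        empty_subj = pd.DataFrame(
            columns=["diabetes_status", "diagnosis_route", "time_zero"],
            index=pd.Index([], name="subject_id"),
        )
        return LongitudinalDataset(records=raw.copy(), subjects=empty_subj), flow

    flags = _subject_flags(raw, first_ogtt_phase)
    remaining = flags.index
    for label, col in zip(
        EXCLUSION_STEPS, ["lost", "prevalent", "not_assessable", "no_bmi"]
    ):
        violating = flags.loc[remaining, col]
        flow.add(label, int(violating.sum()))
        remaining = remaining[~violating.values]

    records = raw[
        raw["subject_id"].isin(remaining) & (raw["phase"] >= first_ogtt_phase)
    ].copy()
    subjects = _ascertain_status(records)

    tz = records["subject_id"].map(subjects["time_zero"])
    records["t"] = (
        (records["exam_date"] - tz) / pd.Timedelta(days=1)
    ) / DAYS_PER_YEAR
    post = records["t"] > 0
    if post.any():
        logger.warning(
            "dropping %d examination records after time zero", int(post.sum())
        )
        records = records[~post]
    records = records.drop(columns=["_glyc"], errors="ignore")

    # Subjects whose only BMI measurements were after time zero cannot enter
    # the trajectory models; dropped as a trailing flow step when present.
    has_bmi = records.groupby("subject_id")["bmi"].apply(lambda s: s.notna().any())
    bad = has_bmi.index[~has_bmi]
    if len(bad) > 0:
        warnings.warn(
            f"{len(bad)} subject(s) have no BMI measurement before time zero",
            stacklevel=2,
        )
        flow.add("no BMI measurement before time zero", len(bad))
        records = records[~records["subject_id"].isin(bad)]
        subjects = subjects.drop(index=bad)

    return LongitudinalDataset(records=records, subjects=subjects), flow
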