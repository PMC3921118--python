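"""Seeded synthetic longitudinal cohorts with known latent-class structure.

Emulates the design of a long-running occupational cohort with clinical
examinations roughly five years apart: an incident-diabetes population whose
BMI follows one of a small number of class-specific cubic polynomials on the
backward time axis (t = 0 at diagnosis), a large diabetes-free reference
group with a slowly drifting BMI, Gaussian random intercept-and-slope
heterogeneity between subjects, Gaussian residual noise, and optional
correlated risk-factor tracks (some generated on the log scale).

Every draw flows from a single integer seed through named substreams, so
adding an outcome track never perturbs the cohort draw.  The ground-truth
class labels and random effects are returned separately from the dataset and
are never consumed by fitting code.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lctraj.cohort import DAYS_PER_YEAR, LongitudinalDataset

#: Class proportions implied by modal class sizes 604 / 15 / 26 of 645.
DEFAULT_PROPORTIONS = (604 / 645, 15 / 645, 26 / 645)

#: Mean BMI trajectory per latent class on backward time, as polynomial
#: coefficients (level at t = 0, then t, t^2, t^3).  Levels at diagnosis are
#: 28.1 / 41.1 / 32.7 kg/m^2 for the stable-overweight, progressive-weight-
#: gain and persistently-obese classes respectively.
DEFAULT_CLASS_COEF = (
    (28.1, 0.095, 0.0, 0.0),
    (41.1, 2.285, 0.268, 0.011),
    (32.7, 0.016, 0.060, 0.005),
)

#: Diabetes-free reference trajectory: 24.5 -> 26.2 kg/m^2 over 18 years.
DEFAULT_FREE_COEF = (26.2, 0.094, 0.0, 0.0)


@dataclass
class OutcomeTrack:
    """One synthetic risk-factor track.

    ``coef`` maps group label ("class_1", ..., "free") to polynomial
    coefficients in backward time (level at t = 0 first).  With
    ``log_scale`` the polynomial describes the natural-log mean and values
    are exponentiated after adding subject and residual noise.
    """

    name: str
    coef: dict[str, tuple[float, ...]]
    sd_intercept: float = 0.5
    sd_resid: float = 0.5
    log_scale: bool = False
    missing_rate: float = 0.0


def default_outcome_tracks() -> list[OutcomeTrack]:
    """Two illustrative tracks: systolic blood pressure (identity scale) and
    fasting insulin (log scale, higher and steeper in the heavier classes)."""
    return [
        OutcomeTrack(
            name="sbp",
            coef={
                "class_1": (125.0, 0.46, 0.0, 0.0),
                "class_2": (135.0, 1.16, 0.0, 0.0),
                "class_3": (132.0, 0.7, 0.0, 0.0),
                "free": (121.0, 0.25, 0.0, 0.0),
            },
            sd_intercept=8.0,
            sd_resid=7.0,
        ),
        OutcomeTrack(
            name="fasting_insulin",
            coef={
                "class_1": (2.3, 0.026, 0.0, 0.0),
                "class_2": (3.4, 0.082, 0.0, 0.0),
                "class_3": (2.9, 0.014, 0.0, 0.0),
                "free": (1.8, 0.016, 0.0, 0.0),
            },
            sd_intercept=0.35,
            sd_resid=0.3,
            log_scale=True,
        ),
    ]


@dataclass
class SyntheticConfig:
    """Full data-generating specification for a synthetic cohort."""

    n_subjects: int = 645  # incident-diabetes population
    n_diabetes_free: int = 6060
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    class_coef: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_COEF
    free_coef: tuple[float, ...] = DEFAULT_FREE_COEF
    sd_intercept: float = 3.0  # kg/m^2
    sd_slope: float = 0.15  # kg/m^2 per year
    re_correlation: float = 0.2
    sd_resid: float = 0.8  # kg/m^2
    n_visits: int = 4
    visit_spacing: float = 5.0  # years
    visit_jitter: float = 1.0  # uniform +/- years
    age_t0_mean: float = 60.0
    age_t0_sd: float = 7.0
    male_fraction: float = 0.72
    sex_effect: float = -0.5  # BMI shift for men (sex = 1)
    age_effect: float = 0.02  # BMI per year of age at time zero
    phase_effects: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
    dropout: float = 0.1  # per-visit missingness, at least one visit kept
    outcomes: list[OutcomeTrack] = field(default_factory=default_outcome_tracks)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-8 or np.any(props <= 0):
            raise ValueError("class proportions must be a positive simplex")
        if len(self.class_coef) != len(props):
            raise ValueError("one coefficient set per class required")
        if min(self.sd_intercept, self.sd_slope, self.sd_resid) <= 0:
            raise ValueError("all SDs must be positive")
        if self.n_subjects < len(props):
            raise ValueError("fewer subjects than classes")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream: independent of any other named stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def _polyval_backward(coef, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for k, c in enumerate(coef):
        out += c * t**k
    return out


def _simulate_group(
    config: SyntheticConfig,
    rng_visits: np.random.Generator,
    rng_subject: np.random.Generator,
    n: int,
    coef_lookup,
    prefix: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one population (incident classes or diabetes-free)."""
    ids = np.array([f"{prefix}{i:06d}" for i in range(n)])
    classes = coef_lookup(rng_subject, n)  # (labels, coef rows)
    labels, coef_rows = classes

    cov = np.array(
        [
            [config.sd_intercept**2, config.re_correlation * config.sd_intercept * config.sd_slope],
            [config.re_correlation * config.sd_intercept * config.sd_slope, config.sd_slope**2],
        ]
    )
    b = rng_subject.multivariate_normal(np.zeros(2), cov, size=n)
    age_t0 = rng_subject.normal(config.age_t0_mean, config.age_t0_sd, size=n)
    sex = (rng_subject.random(n) < config.male_fraction).astype(int)

    # visit schedule anchored with the last exam near t = 0
    base = -config.visit_spacing * np.arange(config.n_visits - 1, -1, -1)
    jitter = rng_visits.uniform(-config.visit_jitter, config.visit_jitter, (n, config.n_visits))
    t = np.minimum(base[None, :] + jitter, 0.0)
    t[:, -1] = np.minimum(t[:, -1], 0.0)

    keep = rng_visits.random((n, config.n_visits)) >= config.dropout
    none_kept = ~keep.any(axis=1)
    if none_kept.any():
        forced = rng_visits.integers(0, config.n_visits, size=int(none_kept.sum()))
        keep[np.where(none_kept)[0], forced] = True

    eps = rng_subject.normal(0.0, config.sd_resid, (n, config.n_visits))
    coef_mat = np.asarray(coef_rows, dtype=float)  # (n, K)
    mean = np.zeros_like(t)
    for k in range(coef_mat.shape[1]):
        mean += coef_mat[:, k : k + 1] * t**k
    bmi = (
        mean
        + config.sex_effect * sex[:, None]
        + config.age_effect * (age_t0[:, None] - config.age_t0_mean)
        + np.asarray(config.phase_effects)[None, : config.n_visits]
        + b[:, 0:1]
        + b[:, 1:2] * t
        + eps
    )

    phases = np.array([3, 5, 7, 9][: config.n_visits])
    tz = pd.Timestamp("2008-06-30")
    rows = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, config.n_visits),
            "phase": np.tile(phases, n),
            "t": t.ravel(),
            "age": (age_t0[:, None] + t).ravel(),
            "sex": np.repeat(sex, config.n_visits),
            "bmi": bmi.ravel(),
        }
    )
    rows["exam_date"] = tz + pd.to_timedelta(
        np.round(rows["t"] * DAYS_PER_YEAR), unit="D"
    )
    rows = rows[keep.ravel()].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "true_class": labels,
            "b_intercept": b[:, 0],
            "b_slope": b[:, 1],
            "age_t0": age_t0,
            "sex": sex,
        }
    )
    return rows, truth


def generate_cohort(config: SyntheticConfig) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Draw a synthetic cohort with known latent structure.

    Returns the dataset (records with backward time ``t`` and a per-subject
    status table) and the ground-truth record (true class, random effects).
    Incident subjects carry labels ``1..G``; diabetes-free subjects label 0.
    """
    rng_class = _stream(config.seed, "class")
    rng_re = _stream(config.seed, "random_effects")
    rng_visits = _stream(config.seed, "visits")

    props = np.asarray(config.class_proportions)
    coef_arr = [np.asarray(c, dtype=float) for c in config.class_coef]
    drawn_classes = rng_class.choice(len(props), size=config.n_subjects, p=props)

    def incident_lookup(rng, n):
        labels = drawn_classes + 1
        return labels, np.stack([coef_arr[c] for c in drawn_classes])

    inc_rows, inc_truth = _simulate_group(
        config, rng_visits, rng_re, config.n_subjects, incident_lookup, "D"
    )

    frames, truths = [inc_rows], [inc_truth]
    if config.n_diabetes_free > 0:
        rng_free = _stream(config.seed, "free")
        rng_free_visits = _stream(config.seed, "free_visits")
        free_coef = np.asarray(config.free_coef, dtype=float)

        def free_lookup(rng, n):
            return np.zeros(n, dtype=int), np.tile(free_coef, (n, 1))

        free_rows, free_truth = _simulate_group(
            config, rng_free_visits, rng_free, config.n_diabetes_free, free_lookup, "F"
        )
        frames.append(free_rows)
        truths.append(free_truth)

    records = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)

    subj = truth.set_index("subject_id")
    subjects = pd.DataFrame(index=subj.index)
    incident = subj["true_class"] > 0
    subjects["diabetes_status"] = np.where(incident, "incident", "diabetes-free")
    subjects["diagnosis_route"] = np.where(incident, "screen", "none")
    # all subjects share the scheduled end-of-follow-up anchor, so that
    # t == (exam_date - time_zero) in years up to day rounding
    subjects["time_zero"] = pd.Timestamp("2008-06-30")

    dataset = LongitudinalDataset(records=records, subjects=subjects)
    return dataset, truth


def generate_outcome_tracks(
    config: SyntheticConfig, dataset: LongitudinalDataset, truth: pd.DataFrame
) -> LongitudinalDataset:
    """Add the configured risk-factor tracks to a generated cohort.

    Each outcome is a class-specific polynomial mean plus a subject random
    intercept and residual noise; log-scale outcomes are generated on the
    log scale and exponentiated.  Missingness is injected completely at
    random at the configured per-outcome rate.
    """
    records = dataset.records.copy()
    label_by_subject = truth.set_index("subject_id")["true_class"]
    group = label_by_subject.reindex(records["subject_id"]).to_numpy()
    group_names = np.where(group == 0, "free", [f"class_{g}" for g in group])
    t = records["t"].to_numpy()

    for track in config.outcomes:
        if track.name in records.columns:
            raise ValueError(f"outcome name collides with existing column: {track.name}")
        rng = _stream(config.seed, f"outcome:{track.name}")
        intercepts = pd.Series(
            rng.normal(0.0, track.sd_intercept, size=len(label_by_subject)),
            index=label_by_subject.index,
        )
        mean = np.empty(len(records))
        for name, coef in track.coef.items():
            sel = group_names == name
            mean[sel] = _polyval_backward(np.asarray(coef, float), t[sel])
        values = (
            mean
            + intercepts.reindex(records["subject_id"]).to_numpy()
            + rng.normal(0.0, track.sd_resid, size=len(records))
        )
        if track.log_scale:
            values = np.exp(values)
        if track.missing_rate > 0:
            values = np.where(
                rng.random(len(values)) < track.missing_rate, np.nan, values
            )
        records[track.name] = values
    return LongitudinalDataset(records=records, subjects=dataset.subjects.copy())


# ---------------------------------------------------------------------------
# Purpose-built raw cohort for exclusion-flow accounting


def generate_flow_cohort(
    n_total: int = 9181,
    n_lost: int = 830,
    n_prevalent: int = 211,
    n_unassessable: int = 776,
    n_no_bmi: int = 659,
    n_incident: int = 645,
    seed: int = 0,
    overlap_prevalent_unassessable: int = 0,
) -> pd.DataFrame:
    """Raw long-format cohort with prescribed exclusion-rule violators.

    Builds ``n_total`` subjects of whom exactly ``n_lost`` never attend an
    OGTT phase, ``n_prevalent`` have diabetes at their first in-study
    examination, ``n_unassessable`` have no valid OGTT and no diagnosis
    outside the study, and ``n_no_bmi`` lack any BMI measurement; the groups
    are disjoint unless ``overlap_prevalent_unassessable`` shifts that many
    prevalent subjects to also violate the assessability rule (they must
    still be counted once, at the prevalence step).  Of the remaining
    subjects, ``n_incident`` develop screen-detected diabetes at the final
    phase.
    """
    n_excl = n_lost + n_prevalent + n_unassessable + n_no_bmi
    n_retained = n_total - n_excl
    if n_retained < n_incident:
        raise ValueError("not enough retained subjects for the incident count")
    rng = _stream(seed, "flow")

    ids = np.array([f"P{i:06d}" for i in range(n_total)])
    phase_dates = {
        1: pd.Timestamp("1986-06-01"),
        3: pd.Timestamp("1992-06-01"),
        5: pd.Timestamp("1997-06-01"),
        7: pd.Timestamp("2003-06-01"),
        9: pd.Timestamp("2008-06-01"),
    }

    frames = []

    def make_block(block_ids, phases, **cols):
        n = len(block_ids)
        if n == 0:
            return
        base = pd.DataFrame(
            {
                "subject_id": np.repeat(block_ids, len(phases)),
                "phase": np.tile(phases, n),
            }
        )
        offsets = rng.integers(-120, 120, size=len(base))
        base["exam_date"] = (
            base["phase"].map(phase_dates)
            + pd.to_timedelta(offsets, unit="D")
        )
        age0 = np.repeat(rng.normal(49.0, 6.0, size=n), len(phases))
        years = (base["exam_date"] - phase_dates[3]) / pd.Timedelta(days=DAYS_PER_YEAR)
        base["age"] = age0 + years
        base["sex"] = np.repeat((rng.random(n) < 0.72).astype(int), len(phases))
        for name, value in cols.items():
            if name == "self_report_diabetes_date":
                base[name] = pd.Series(value, index=base.index, dtype="datetime64[ns]")
            else:
                base[name] = value
        frames.append(base)

    cursor = 0

    def take(k):
        nonlocal cursor
        out = ids[cursor : cursor + k]
        cursor += k
        return out

    # 1) lost before the first OGTT phase: only a phase-1 record
    make_block(
        take(n_lost), [1], fpg=np.nan, pg2h=np.nan, fasting_hours=np.nan,
        bmi=26.0, self_report_diabetes_date=pd.NaT,
    )
    # 2) prevalent diabetes at first in-study examination
    n_prev_plain = n_prevalent - overlap_prevalent_unassessable
    make_block(
        take(n_prev_plain), [3, 5], fpg=8.2, pg2h=12.5, fasting_hours=10.0,
        bmi=29.0, self_report_diabetes_date=pd.NaT,
    )
    # prevalent by doctor diagnosis, OGTTs all invalid: violates rules 2 and 3,
    # must be counted at rule 2 only
    overlap_ids = take(overlap_prevalent_unassessable)
    make_block(
        overlap_ids, [3, 5], fpg=np.nan, pg2h=np.nan, fasting_hours=6.0,
        bmi=29.0, self_report_diabetes_date=pd.Timestamp("1990-01-01"),
    )
    # 3) diabetes status never assessable: short fasts, no outside diagnosis
    make_block(
        take(n_unassessable), [3, 5], fpg=np.nan, pg2h=np.nan, fasting_hours=6.0,
        bmi=27.0, self_report_diabetes_date=pd.NaT,
    )
    # 4) no BMI measurement at any phase
    make_block(
        take(n_no_bmi), [3, 5], fpg=5.2, pg2h=5.4, fasting_hours=10.0,
        bmi=np.nan, self_report_diabetes_date=pd.NaT,
    )
    # retained: incident (diabetes-free until a diagnosing OGTT at phase 9)
    inc_ids = take(n_incident)
    n = len(inc_ids)
    inc = pd.DataFrame(
        {
            "subject_id": np.repeat(inc_ids, 4),
            "phase": np.tile([3, 5, 7, 9], n),
        }
    )
    inc["exam_date"] = inc["phase"].map(phase_dates) + pd.to_timedelta(
        rng.integers(-120, 120, size=len(inc)), unit="D"
    )
    age0 = np.repeat(rng.normal(49.0, 6.0, size=n), 4)
    years = (inc["exam_date"] - phase_dates[3]) / pd.Timedelta(days=DAYS_PER_YEAR)
    inc["age"] = age0 + years
    inc["sex"] = np.repeat((rng.random(n) < 0.72).astype(int), 4)
    inc["fpg"] = np.where(inc["phase"] == 9, 7.8, 5.5)
    inc["pg2h"] = np.where(inc["phase"] == 9, 12.0, 6.0)
    inc["fasting_hours"] = 10.0
    inc["bmi"] = np.repeat(rng.normal(28.0, 3.5, size=n), 4)
    inc["self_report_diabetes_date"] = pd.NaT
    frames.append(inc)
    # retained: diabetes-free throughout
    make_block(
        take(n_retained - n_incident), [3, 5, 7, 9], fpg=5.2, pg2h=5.2,
        fasting_hours=10.0, bmi=25.3, self_report_diabetes_date=pd.NaT,
    )

    raw = pd.concat(frames, ignore_index=True)
    return raw.sample(frac=1.0, random_state=int(seed) % 2**32).reset_index(drop=True)
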