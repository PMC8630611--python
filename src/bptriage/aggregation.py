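"""Per-subject aggregation of reading-level blood-pressure data.

Office, home, and ambulatory BP are measured on very different schedules
(three clinic visits; seven days of morning/evening self-measurement;
25 h of automated half-hourly readings).  This module reduces each
subject's raw readings to the single office / home / daytime-ambulatory
BP pairs the triage algorithm consumes, applying the protocol's discard
and validity rules:

* office — the index arm (higher-BP arm) is chosen and all its readings
  averaged;
* home — the first evening and second morning are discarded, the first
  two readings of each session averaged, and at least five days of
  morning and evening duplicate measurements are required for validity;
* ambulatory — a recording is valid only when more than 70 % of attempts
  succeeded with at least 14 daytime and 7 nighttime readings, and the
  reference value is the unweighted mean over the daytime clock window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BPPair",
    "ClockWindow",
    "ScheduleSpec",
    "SubjectMeasurements",
    "AggregatedSubject",
    "MissingArmError",
    "InvalidMeasurementError",
    "READINGS_COLUMNS",
    "DEVELOPMENT_SCHEDULE",
    "VALIDATION_SCHEDULE",
    "aggregate_office",
    "validate_home",
    "aggregate_home",
    "validate_ambulatory",
    "aggregate_window",
    "aggregate_all_valid",
    "aggregate_subject",
    "aggregate_cohort",
    "subjects_to_frame",
]

#: Canonical column order of the reading-level table (one row per cuff
#: inflation).  Fields not applicable to a modality are left empty:
#: office rows use arm/visit/reading_index, home rows use
#: day/session/reading_index, ambulatory rows use timestamp/valid.
READINGS_COLUMNS = [
    "subject_id",
    "modality",
    "arm",
    "visit",
    "day",
    "session",
    "reading_index",
    "timestamp",
    "sbp",
    "dbp",
    "valid",
]

Scheme = Literal["development", "validation"]


class MissingArmError(ValueError):
    """Raised when a required visit lacks readings from one arm."""


class InvalidMeasurementError(ValueError):
    """Raised when aggregation is requested on data that fails validity rules."""


@dataclass(frozen=True)
class BPPair:
    """A systolic/diastolic pressure pair in mmHg."""

    sbp: float
    dbp: float

    def __iter__(self):
        yield self.sbp
        yield self.dbp


# A clock window is a pair of "HH:MM" strings, half-open [start, end).
# A window whose start is later than its end wraps past midnight.
ClockWindow = tuple[str, str]


def clock_minutes(timestamp: str) -> int:
    """Minutes after midnight for an ``HH:MM`` clock string."""
    hh, mm = timestamp.split(":")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"not a 24-hour HH:MM clock time: {timestamp!r}")
    return 60 * h + m


def in_window(timestamp: str, window: ClockWindow) -> bool:
    """Whether a clock time falls in the half-open window [start, end)."""
    t = clock_minutes(timestamp)
    start, end = (clock_minutes(w) for w in window)
    if start <= end:
        return start <= t < end
    return t >= start or t < end  # wraps midnight


def _window_length(window: ClockWindow) -> int:
    start, end = (clock_minutes(w) for w in window)
    return (end - start) % (24 * 60)


@dataclass(frozen=True)
class ScheduleSpec:
    """Measurement schedule for one study protocol.

    Defaults follow the development protocol: three office visits with
    triplicate readings, seven home days with morning and evening
    triplicate sessions, and 25 h of ambulatory monitoring at 30-min
    intervals with a 10:00-20:00 daytime and 00:00-06:00 nighttime
    window.
    """

    office_visits: int = 3
    office_readings_per_visit: int = 3
    home_days: int = 7
    home_sessions_per_day: int = 2
    home_readings_per_session: int = 3
    ambulatory_interval_min: int = 30
    ambulatory_duration_h: float = 25.0
    daytime_window: ClockWindow = ("10:00", "20:00")
    nighttime_window: ClockWindow = ("00:00", "06:00")

    def __post_init__(self) -> None:
        counts = (
            self.office_visits,
            self.office_readings_per_visit,
            self.home_days,
            self.home_sessions_per_day,
            self.home_readings_per_session,
            self.ambulatory_interval_min,
        )
        if any(int(c) < 1 for c in counts):
            raise ValueError("all schedule counts must be >= 1")
        if self.ambulatory_duration_h <= 0:
            raise ValueError("ambulatory duration must be positive")
        for w in (self.daytime_window, self.nighttime_window):
            if _window_length(w) == 0:
                raise ValueError(f"zero-length clock window: {w}")
        # windows must not overlap (checked on the clock circle)
        day_start = clock_minutes(self.daytime_window[0])
        for offset in range(0, _window_length(self.daytime_window)):
            t = (day_start + offset) % (24 * 60)
            hh, mm = divmod(t, 60)
            if in_window(f"{hh:02d}:{mm:02d}", self.nighttime_window):
                raise ValueError("daytime and nighttime windows overlap")

    @property
    def ambulatory_attempts(self) -> int:
        return int(self.ambulatory_duration_h * 60 // self.ambulatory_interval_min) + 1


DEVELOPMENT_SCHEDULE = ScheduleSpec()
VALIDATION_SCHEDULE = ScheduleSpec(daytime_window=("09:00", "21:00"))


@dataclass
class SubjectMeasurements:
    """All raw readings of one subject, as a table in READINGS_COLUMNS order."""

    subject_id: str
    readings: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in READINGS_COLUMNS if c not in self.readings.columns]
        if missing:
            raise ValueError(f"readings table lacks columns {missing}")
        ids = self.readings["subject_id"].unique()
        if len(ids) > 1 or (len(ids) == 1 and ids[0] != self.subject_id):
            raise ValueError(
                f"readings of subject {self.subject_id!r} carry foreign subject ids {list(ids)}"
            )

    def of_modality(self, modality: str) -> pd.DataFrame:
        return self.readings[self.readings["modality"] == modality]


@dataclass(frozen=True)
class AggregatedSubject:
    """Per-subject office / home / ambulatory BP summary.

    ``home`` and the ambulatory pairs are ``None`` whenever the
    corresponding validity flag is false; office BP is always present.
    """

    subject_id: str
    office: BPPair
    home: Optional[BPPair]
    daytime_abp: Optional[BPPair]
    abp_24h: Optional[BPPair]
    home_valid: bool
    abp_valid: bool
    index_arm: str

    def __post_init__(self) -> None:
        if (self.home is not None) != self.home_valid:
            raise ValueError("home BP present iff home_valid")
        if (self.daytime_abp is not None) != self.abp_valid:
            raise ValueError("daytime ambulatory BP present iff abp_valid")


def _arm_mean(df: pd.DataFrame) -> BPPair:
    return BPPair(float(df["sbp"].mean()), float(df["dbp"].mean()))


def _pick_index_arm(means: dict[str, BPPair]) -> str:
    """Higher mean SBP decides; ties fall to higher mean DBP, then right arm."""
    left, right = means["left"], means["right"]
    if left.sbp != right.sbp:
        return "left" if left.sbp > right.sbp else "right"
    if left.dbp != right.dbp:
        return "left" if left.dbp > right.dbp else "right"
    return "right"


def aggregate_office(
    readings: pd.DataFrame,
    scheme: Scheme = "development",
    subject_id: str = "?",
) -> tuple[BPPair, str]:
    """Office BP and index arm from office readings.

    development
        The index arm is the arm with the higher visit-1 mean; office BP
        is the mean of every index-arm reading across all visits.
    validation
        Per-arm means are taken over all visits first; the higher-mean
        arm becomes the index arm and its overall mean the office BP.
    """
    office = readings[readings["modality"] == "office"]
    if office.empty:
        raise MissingArmError(f"subject {subject_id}: no office readings")

    if scheme == "development":
        visit1 = office[office["visit"] == 1]
        arm_means = {}
        for arm in ("left", "right"):
            arm_df = visit1[visit1["arm"] == arm]
            if arm_df.empty:
                raise MissingArmError(
                    f"subject {subject_id}: visit 1 lacks readings from the {arm} arm"
                )
            arm_means[arm] = _arm_mean(arm_df)
        index_arm = _pick_index_arm(arm_means)
        index_df = office[office["arm"] == index_arm]
        return _arm_mean(index_df), index_arm

    if scheme == "validation":
        visits = sorted(office["visit"].dropna().unique())
        arm_means = {}
        for arm in ("left", "right"):
            arm_df = office[office["arm"] == arm]
            for v in visits:
                if arm_df[arm_df["visit"] == v].empty:
                    raise MissingArmError(
                        f"subject {subject_id}: visit {int(v)} lacks readings from the {arm} arm"
                    )
            arm_means[arm] = _arm_mean(arm_df)
        index_arm = _pick_index_arm(arm_means)
        return arm_means[index_arm], index_arm

    raise ValueError(f"unknown office aggregation scheme {scheme!r}")


def _discard_home_sessions(home: pd.DataFrame) -> pd.DataFrame:
    """Drop the day-1 evening and day-2 morning sessions (never analysed)."""
    drop = ((home["day"] == 1) & (home["session"] == "evening")) | (
        (home["day"] == 2) & (home["session"] == "morning")
    )
    return home[~drop]


def validate_home(readings: pd.DataFrame) -> bool:
    """At least 5 days each of morning and evening duplicate measurements.

    The count is taken after the first-evening / second-morning discard;
    "duplicate" means a session retaining >= 2 readings.
    """
    home = readings[readings["modality"] == "home"]
    if home.empty:
        return False
    kept = _discard_home_sessions(home)
    session_sizes = kept.groupby(["day", "session"], observed=True).size()
    ok = session_sizes[session_sizes >= 2]
    days_with = {
        session: ok.index[ok.index.get_level_values("session") == session].get_level_values("day").nunique()
        for session in ("morning", "evening")
    }
    return days_with["morning"] >= 5 and days_with["evening"] >= 5


def aggregate_home(readings: pd.DataFrame) -> BPPair:
    """Home BP: mean over sessions of the mean of each session's first two readings.

    Sessions surviving the discard rule contribute the average of their
    first and second readings (a single-reading session contributes that
    reading; any third reading is ignored); the home BP is the unweighted
    mean over session values, systolic and diastolic separately.
    """
    if not validate_home(readings):
        raise InvalidMeasurementError(
            "home readings fail the 5-day duplicate-measurement validity rule"
        )
    home = _discard_home_sessions(readings[readings["modality"] == "home"])
    first_two = home[home["reading_index"] <= 2]
    per_session = first_two.groupby(["day", "session"], observed=True)[["sbp", "dbp"]].mean()
    return BPPair(float(per_session["sbp"].mean()), float(per_session["dbp"].mean()))


def validate_ambulatory(readings: pd.DataFrame, schedule: ScheduleSpec) -> bool:
    """Strictly more than 70 % valid attempts, >= 14 daytime and >= 7 nighttime readings."""
    amb = readings[readings["modality"] == "ambulatory"]
    if amb.empty:
        return False
    attempts = len(amb)
    valid = amb[amb["valid"].astype(bool)]
    if len(valid) / attempts <= 0.70:
        return False
    ts = valid["timestamp"]
    n_day = int(ts.map(lambda t: in_window(t, schedule.daytime_window)).sum())
    n_night = int(ts.map(lambda t: in_window(t, schedule.nighttime_window)).sum())
    return n_day >= 14 and n_night >= 7


def aggregate_window(readings: pd.DataFrame, window: ClockWindow) -> BPPair:
    """Unweighted mean of valid ambulatory readings inside a clock window."""
    amb = readings[readings["modality"] == "ambulatory"]
    valid = amb[amb["valid"].astype(bool)]
    inside = valid[valid["timestamp"].map(lambda t: in_window(t, window))]
    if inside.empty:
        raise InvalidMeasurementError(f"no valid ambulatory readings in window {window}")
    return _arm_mean(inside)


def aggregate_all_valid(readings: pd.DataFrame) -> BPPair:
    """Mean over every valid ambulatory reading (the 24-h / full-span mean)."""
    amb = readings[readings["modality"] == "ambulatory"]
    valid = amb[amb["valid"].astype(bool)]
    if valid.empty:
        raise InvalidMeasurementError("no valid ambulatory readings")
    return _arm_mean(valid)


def aggregate_subject(
    subject: SubjectMeasurements,
    scheme: Scheme = "development",
    schedule: ScheduleSpec = DEVELOPMENT_SCHEDULE,
) -> AggregatedSubject:
    """Reduce one subject's readings to an :class:`AggregatedSubject`."""
    office, index_arm = aggregate_office(
        subject.readings, scheme=scheme, subject_id=subject.subject_id
    )
    home_valid = validate_home(subject.readings)
    home = aggregate_home(subject.readings) if home_valid else None
    abp_valid = validate_ambulatory(subject.readings, schedule)
    daytime = abp_24h = None
    if abp_valid:
        daytime = aggregate_window(subject.readings, schedule.daytime_window)
        abp_24h = aggregate_all_valid(subject.readings)
    return AggregatedSubject(
        subject_id=subject.subject_id,
        office=office,
        home=home,
        daytime_abp=daytime,
        abp_24h=abp_24h,
        home_valid=home_valid,
        abp_valid=abp_valid,
        index_arm=index_arm,
    )


def aggregate_cohort(
    subjects: Iterable[SubjectMeasurements],
    scheme: Scheme = "development",
    schedule: ScheduleSpec = DEVELOPMENT_SCHEDULE,
) -> list[AggregatedSubject]:
    return [aggregate_subject(s, scheme=scheme, schedule=schedule) for s in subjects]


def subjects_to_frame(subjects: Sequence[AggregatedSubject]) -> pd.DataFrame:
    """One row per aggregated subject (the subjects.csv layout)."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "office_sbp": s.office.sbp,
                "office_dbp": s.office.dbp,
                "home_sbp": s.home.sbp if s.home else np.nan,
                "home_dbp": s.home.dbp if s.home else np.nan,
                "daytime_sbp": s.daytime_abp.sbp if s.daytime_abp else np.nan,
                "daytime_dbp": s.daytime_abp.dbp if s.daytime_abp else np.nan,
                "abp24_sbp": s.abp_24h.sbp if s.abp_24h else np.nan,
                "abp24_dbp": s.abp_24h.dbp if s.abp_24h else np.nan,
                "home_valid": s.home_valid,
                "abp_valid": s.abp_valid,
                "index_arm": s.index_arm,
            }
        )
    return pd.DataFrame(rows)
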