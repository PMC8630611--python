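"""Shared fixtures: synthetic cohorts and hand-built reading tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from bptriage.aggregation import READINGS_COLUMNS, SubjectMeasurements, aggregate_cohort
from bptriage.synthetic import development_params, generate_screened_cohort


def readings_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a readings table from partial row dicts (missing fields filled)."""
    full = []
    for r in rows:
        base = {
            "subject_id": "S1",
            "modality": "office",
            "arm": "",
            "visit": pd.NA,
            "day": pd.NA,
            "session": "",
            "reading_index": pd.NA,
            "timestamp": "",
            "sbp": 120.0,
            "dbp": 80.0,
            "valid": True,
        }
        base.update(r)
        full.append(base)
    df = pd.DataFrame(full, columns=READINGS_COLUMNS)
    for col in ("visit", "day", "reading_index"):
        df[col] = df[col].astype("Int64")
    df["valid"] = df["valid"].astype(bool)
    return df


def office_rows(sbp, dbp, visit=1, arm="right", n=3, subject_id="S1"):
    return [
        {
            "subject_id": subject_id,
            "modality": "office",
            "arm": arm,
            "visit": visit,
            "reading_index": k,
            "sbp": float(sbp),
            "dbp": float(dbp),
        }
        for k in range(1, n + 1)
    ]


def home_rows(sbp, dbp, day, session, n=3, subject_id="S1"):
    return [
        {
            "subject_id": subject_id,
            "modality": "home",
            "day": day,
            "session": session,
            "reading_index": k,
            "sbp": float(sbp),
            "dbp": float(dbp),
        }
        for k in range(1, n + 1)
    ]


def ambulatory_rows(sbp, dbp, timestamps, valid=True, subject_id="S1"):
    return [
        {
            "subject_id": subject_id,
            "modality": "ambulatory",
            "timestamp": ts,
            "sbp": float(sbp),
            "dbp": float(dbp),
            "valid": valid,
        }
        for ts in timestamps
    ]


def full_home_grid(sbp=130.0, dbp=80.0, days=7, subject_id="S1"):
    rows = []
    for day in range(1, days + 1):
        for session in ("morning", "evening"):
            rows += home_rows(sbp, dbp, day, session, subject_id=subject_id)
    return rows


@dataclass
class DevCohort:
    params: object
    subjects: list
    profiles: list
    aggregated: list
    cohort: list  # aggregated subjects passing all validity filters


@pytest.fixture(scope="session")
def dev_cohort() -> DevCohort:
    """Development-preset screened cohort at the standard study size."""
    params = development_params(n_subjects=2000, seed=1)
    subjects, profiles = generate_screened_cohort(params)
    aggregated = aggregate_cohort(subjects)
    cohort = [a for a in aggregated if a.home_valid and a.abp_valid]
    return DevCohort(params, subjects, profiles, aggregated, cohort)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort with all measurement noise switched off."""
    params = development_params(
        n_subjects=60,
        seed=3,
        reading_noise_sd={"office": 0.0, "home": 0.0, "ambulatory": 0.0},
        office_visit_sd=0.0,
        missing_session_rate=0.0,
        circadian_offsets=(0.0, 0.0),
    )
    subjects, profiles = generate_screened_cohort(params)
    return params, subjects, profiles
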