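"""File schemas: readings.csv, subjects.csv, zone tables, zones.json.

The reading-level CSV has the fixed header
``subject_id, modality, arm, visit, day, session, reading_index,
timestamp, sbp, dbp, valid`` with fields left empty where a modality
does not use them, and a leading versioned comment line.  Reading the
file back yields the same in-memory representation that was written
(round-trip identity), and malformed rows are collected and reported
together with their row numbers rather than failing one at a time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .aggregation import READINGS_COLUMNS, AggregatedSubject, SubjectMeasurements, subjects_to_frame
from .cascade import PHENOTYPE_ORDER, ZONE_ORDER, ZonePhenotypeTable
from .metrics import DiagnosticMetrics
from .zones import ThresholdPair, ZoneBoundaries

__all__ = [
    "SchemaError",
    "READINGS_SCHEMA_VERSION",
    "write_readings_csv",
    "read_readings_csv",
    "write_subjects_csv",
    "write_zone_table_csv",
    "read_zone_table_csv",
    "write_zones_json",
    "read_zones_json",
    "format_metrics_frame",
]

READINGS_SCHEMA_VERSION = "bptriage-readings v1"

_MODALITIES = {"office", "home", "ambulatory"}
_INT_FIELDS = ("visit", "day", "reading_index")


class SchemaError(ValueError):
    """One or more rows violated the readings schema."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        super().__init__(f"{len(errors)} schema violation(s):\n{preview}{more}")


def write_readings_csv(subjects: Sequence[SubjectMeasurements], path: str | Path) -> None:
    path = Path(path)
    frames = [s.readings for s in subjects]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=READINGS_COLUMNS)
    out = df.copy()
    for col in _INT_FIELDS:
        out[col] = out[col].astype("Int64").astype(object)
    out["valid"] = np.where(
        out["modality"] == "ambulatory", out["valid"].astype(bool).astype(int).astype(str), ""
    )
    out["sbp"] = out["sbp"].map(lambda x: f"{x:.3f}")
    out["dbp"] = out["dbp"].map(lambda x: f"{x:.3f}")
    with open(path, "w") as fh:
        fh.write(f"# {READINGS_SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False, na_rep="")


def _parse_rows(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    errors: list[str] = []
    rows = []
    for i, row in raw.iterrows():
        rownum = i + 3  # 1-based, after comment and header lines
        rec = {c: row.get(c) for c in READINGS_COLUMNS}
        modality = str(rec["modality"])
        if modality not in _MODALITIES:
            errors.append(f"row {rownum}: unknown modality {modality!r}")
            continue
        try:
            sbp, dbp = float(rec["sbp"]), float(rec["dbp"])
        except (TypeError, ValueError):
            errors.append(f"row {rownum}: non-numeric sbp/dbp")
            continue
        if not (40 <= sbp <= 300 and 20 <= dbp <= 200):
            errors.append(f"row {rownum}: BP {sbp}/{dbp} outside physiological range")
            continue
        if sbp <= dbp:
            errors.append(f"row {rownum}: sbp {sbp} must exceed dbp {dbp}")
            continue

        def intfield(name):
            v = rec[name]
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                return pd.NA
            return int(float(v))

        def strfield(name):
            v = rec[name]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return ""
            return str(v).strip()

        try:
            parsed = {
                "subject_id": strfield("subject_id"),
                "modality": modality,
                "arm": strfield("arm"),
                "visit": intfield("visit"),
                "day": intfield("day"),
                "session": strfield("session"),
                "reading_index": intfield("reading_index"),
                "timestamp": strfield("timestamp"),
                "sbp": sbp,
                "dbp": dbp,
            }
        except (TypeError, ValueError) as exc:
            errors.append(f"row {rownum}: {exc}")
            continue
        if modality == "office":
            if parsed["arm"] not in ("left", "right") or parsed["visit"] is pd.NA or parsed["reading_index"] is pd.NA:
                errors.append(f"row {rownum}: office rows need arm/visit/reading_index")
                continue
            parsed["valid"] = True
        elif modality == "home":
            if parsed["day"] is pd.NA or parsed["session"] not in ("morning", "evening") or parsed["reading_index"] is pd.NA:
                errors.append(f"row {rownum}: home rows need day/session/reading_index")
                continue
            parsed["valid"] = True
        else:  # ambulatory
            ts, valid_raw = parsed["timestamp"], strfield("valid")
            if len(ts.split(":")) != 2 or valid_raw not in ("0", "1"):
                errors.append(f"row {rownum}: ambulatory rows need HH:MM timestamp and valid 0/1")
                continue
            parsed["valid"] = valid_raw == "1"
        rows.append(parsed)
    df = pd.DataFrame(rows, columns=READINGS_COLUMNS)
    if not df.empty:
        for col in _INT_FIELDS:
            df[col] = df[col].astype("Int64")
        df["valid"] = df["valid"].astype(bool)
    return df, errors


def read_readings_csv(path: str | Path) -> list[SubjectMeasurements]:
    """Parse a readings CSV into per-subject tables, collecting row errors."""
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in READINGS_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError([f"header lacks columns {missing}"])
    df, errors = _parse_rows(raw)
    if errors:
        raise SchemaError(errors)
    return [
        SubjectMeasurements(sid, g.reset_index(drop=True))
        for sid, g in df.groupby("subject_id", sort=False)
    ]


def write_subjects_csv(subjects: Sequence[AggregatedSubject], path: str | Path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False, float_format="%.3f")


def write_zone_table_csv(table: ZonePhenotypeTable, path: str | Path) -> None:
    """Phenotype rows x zone columns, plus the arm in a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# bptriage-zone-table v1 arm={table.arm}\n")
        table.counts.rename_axis("phenotype").to_csv(fh)


def read_zone_table_csv(path: str | Path) -> ZonePhenotypeTable:
    with open(path) as fh:
        first = fh.readline()
        arm = "office"
        if first.startswith("#") and "arm=" in first:
            arm = first.split("arm=")[1].strip()
        df = pd.read_csv(fh, index_col="phenotype")
    df.index.name = None
    counts = {p.value: tuple(int(df.at[p.value, z.value]) for z in ZONE_ORDER) for p in PHENOTYPE_ORDER}
    return ZonePhenotypeTable.from_dict(counts, arm=arm)  # type: ignore[arg-type]


def _boundaries_dict(b: ZoneBoundaries) -> dict:
    return {
        "modality": b.modality,
        "lower": {"sbp": b.lower.sbp, "dbp": b.lower.dbp},
        "upper": {"sbp": b.upper.sbp, "dbp": b.upper.dbp},
    }


def write_zones_json(boundaries: Sequence[ZoneBoundaries], path: str | Path) -> None:
    payload = {b.modality: _boundaries_dict(b) for b in boundaries}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_zones_json(path: str | Path) -> dict[str, ZoneBoundaries]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for modality, d in payload.items():
        out[modality] = ZoneBoundaries(
            lower=ThresholdPair(d["lower"]["sbp"], d["lower"]["dbp"]),
            upper=ThresholdPair(d["upper"]["sbp"], d["upper"]["dbp"]),
            modality=modality,  # type: ignore[arg-type]
        )
    return out


def _fmt_pct(ci) -> str:
    if ci is None:
        return "undefined"
    est, lo, hi = ci.percent
    return f"{est:.1f} ({lo:.1f}-{hi:.1f})"


def _fmt_auc(ci) -> str:
    if ci is None:
        return "undefined"
    return f"{ci.estimate:.3f} ({ci.lower:.3f}-{ci.upper:.3f})"


def format_metrics_frame(panels: dict[str, DiagnosticMetrics]) -> pd.DataFrame:
    """Metric rows x strategy columns with "est (lower-upper)" cells."""
    rows = ["sensitivity", "specificity", "auc", "ppv", "npv", "accuracy"]
    data = {}
    for name, m in panels.items():
        data[name] = [
            _fmt_pct(m.sensitivity),
            _fmt_pct(m.specificity),
            _fmt_auc(m.auc),
            _fmt_pct(m.ppv),
            _fmt_pct(m.npv),
            _fmt_pct(m.accuracy),
        ]
    return pd.DataFrame(data, index=rows)
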