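"""Published phenotype-by-zone count tables and fixed zone boundaries.

The development (n = 256) and validation (n = 399) cohorts behind the
triage algorithm were never deposited as raw data, but their full
phenotype-by-zone count tables were published, and every accuracy panel
of the single-arm strategies is exactly recomputable from those counts.
This module bundles the printed counts and the published zone
boundaries (office 130-145 / 80-95 mmHg, home 120-145 / 80-95 mmHg,
stated as intermediate zones 130-144/80-94 and 120-144/80-94) so the
count-level pipeline can be run without any external input.

Note the home-arm phenotype totals differ slightly from the office-arm
totals of the same cohort (development: 47 vs 48 NT, 21 vs 20 WH;
validation: 326 vs 325 reference-positives) because home phenotypes use
the home 135/85 threshold; the tables are evaluated exactly as printed.
"""

from __future__ import annotations

from typing import Literal

from .cascade import ZonePhenotypeTable
from .zones import ThresholdPair, ZoneBoundaries

__all__ = [
    "OFFICE_ZONES",
    "HOME_ZONES",
    "zone_table",
    "fixed_boundaries",
    "ZONE_TABLE_COUNTS",
]

#: Published office zones: normotension < 130/80, hypertension >= 145/95.
OFFICE_ZONES = ZoneBoundaries(
    lower=ThresholdPair(130.0, 80.0), upper=ThresholdPair(145.0, 95.0), modality="office"
)
#: Published home zones: normotension < 120/80, hypertension >= 145/95.
HOME_ZONES = ZoneBoundaries(
    lower=ThresholdPair(120.0, 80.0), upper=ThresholdPair(145.0, 95.0), modality="home"
)

# Counts per phenotype as (normotension zone, intermediate zone, hypertension zone).
ZONE_TABLE_COUNTS: dict[tuple[str, str], dict[str, tuple[int, int, int]]] = {
    ("development", "office"): {
        "NT": (14, 34, 0),
        "WH": (0, 13, 7),
        "MH": (2, 40, 0),
        "SH": (0, 38, 108),
    },
    ("development", "home"): {
        "NT": (24, 23, 0),
        "WH": (0, 17, 4),
        "MH": (9, 31, 0),
        "SH": (0, 76, 72),
    },
    ("validation", "office"): {
        "NT": (12, 33, 0),
        "WH": (0, 19, 10),
        "MH": (4, 58, 0),
        "SH": (0, 88, 175),
    },
    ("validation", "home"): {
        "NT": (10, 45, 0),
        "WH": (0, 18, 0),
        "MH": (10, 59, 0),
        "SH": (0, 140, 117),
    },
}


def zone_table(
    population: Literal["development", "validation"],
    arm: Literal["office", "home"],
) -> ZonePhenotypeTable:
    """The published phenotype-by-zone count table for one cohort and arm."""
    key = (population, arm)
    if key not in ZONE_TABLE_COUNTS:
        raise KeyError(f"no bundled table for population={population!r}, arm={arm!r}")
    return ZonePhenotypeTable.from_dict(ZONE_TABLE_COUNTS[key], arm=arm)


def fixed_boundaries(arm: Literal["office", "home"]) -> ZoneBoundaries:
    return OFFICE_ZONES if arm == "office" else HOME_ZONES
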