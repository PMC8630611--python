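"""Cascading diagnostic strategies and phenotype-by-zone tabulation.

Three sequential strategies diagnose hypertension against the daytime
ambulatory reference:

* ``OBP_ABP`` — office BP decides in its hypertension/normotension
  zones; office-intermediate subjects are resolved by ambulatory BP;
* ``OBP_HBP_ABP`` — office-intermediate subjects fall through to home
  BP zones, and only home-intermediate subjects reach ambulatory BP;
* ``HBP_ABP`` — home BP zones decide directly, ambulatory BP resolving
  the home-intermediate zone.

Because intermediate-zone subjects are resolved by the reference
standard itself, a cascade errs exactly on white-coat hypertensives in
the screening arm's hypertension zone (false positives) and masked
hypertensives in its normotension zone (false negatives).  That makes
the full accuracy panel recomputable from a phenotype-by-zone count
table alone, which is how the published development (n=256) and
validation (n=399) tables are evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregatedSubject, BPPair
from .metrics import ConfusionCounts
from .zones import (
    OFFICE_HT_THRESHOLD,
    OUT_OF_OFFICE_HT_THRESHOLD,
    Phenotype,
    ThresholdPair,
    Zone,
    ZoneBoundaries,
    assign_zone,
    classify_phenotype,
    is_hypertensive,
)

__all__ = [
    "Strategy",
    "CascadeOutcome",
    "ZonePhenotypeTable",
    "MissingStageError",
    "arm_threshold",
    "diagnose",
    "tabulate_zone_phenotypes",
    "evaluate_from_zone_table",
    "evaluate_threshold_alone",
    "evaluate_strategy",
]

PHENOTYPE_ORDER = [Phenotype.NT, Phenotype.WH, Phenotype.MH, Phenotype.SH]
ZONE_ORDER = [Zone.NORMOTENSION, Zone.INTERMEDIATE, Zone.HYPERTENSION]


class Strategy(str, Enum):
    OBP_ABP = "OBP-ABP"
    OBP_HBP_ABP = "OBP-HBP-ABP"
    HBP_ABP = "HBP-ABP"


class MissingStageError(ValueError):
    """A strategy needed a measurement the subject does not have."""


@dataclass(frozen=True)
class CascadeOutcome:
    """Result of running one subject through one strategy."""

    subject_id: str
    diagnosis: Literal["hypertensive", "normotensive"]
    terminal_stage: Literal["office", "home", "ambulatory"]
    office_zone: Optional[Zone] = None
    home_zone: Optional[Zone] = None

    @property
    def hypertensive(self) -> bool:
        return self.diagnosis == "hypertensive"


def arm_threshold(arm: Literal["office", "home"]) -> ThresholdPair:
    """The screening arm's own hypertension threshold (140/90 office, 135/85 home)."""
    return OFFICE_HT_THRESHOLD if arm == "office" else OUT_OF_OFFICE_HT_THRESHOLD


@dataclass(frozen=True)
class ZonePhenotypeTable:
    """Counts of NT/WH/MH/SH within the three zones of one screening arm.

    ``counts`` has phenotype rows (NT, WH, MH, SH) and zone columns
    (normotension, intermediate, hypertension) — the layout of a
    published phenotype-distribution table.
    """

    counts: pd.DataFrame
    arm: Literal["office", "home"]

    def __post_init__(self) -> None:
        want_rows = [p.value for p in PHENOTYPE_ORDER]
        want_cols = [z.value for z in ZONE_ORDER]
        if list(self.counts.index) != want_rows or list(self.counts.columns) != want_cols:
            raise ValueError(
                f"counts must have rows {want_rows} and columns {want_cols}, "
                f"got rows {list(self.counts.index)} cols {list(self.counts.columns)}"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer) or (values < 0).any():
            raise ValueError("zone-phenotype counts must be non-negative integers")

    @classmethod
    def from_dict(
        cls, counts: dict[str, Sequence[int]], arm: Literal["office", "home"]
    ) -> "ZonePhenotypeTable":
        """Build from ``{phenotype: (nt_zone, intermediate, ht_zone)}``."""
        df = pd.DataFrame(
            {z.value: [int(counts[p.value][i]) for p in PHENOTYPE_ORDER] for i, z in enumerate(ZONE_ORDER)},
            index=[p.value for p in PHENOTYPE_ORDER],
        )
        return cls(counts=df, arm=arm)

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cell(self, phenotype: Phenotype, zone: Zone) -> int:
        return int(self.counts.at[phenotype.value, zone.value])


def _reference_bp(
    subject: AggregatedSubject, reference: Literal["daytime", "24h"]
) -> Optional[BPPair]:
    return subject.daytime_abp if reference == "daytime" else subject.abp_24h


def _require(
    value: Optional[BPPair], subject_id: str, strategy: Strategy, stage: str
) -> BPPair:
    if value is None:
        raise MissingStageError(
            f"subject {subject_id}: strategy {strategy.value} requires a valid "
            f"{stage} measurement"
        )
    return value


def diagnose(
    subject: AggregatedSubject,
    strategy: Strategy,
    office_zones: Optional[ZoneBoundaries] = None,
    home_zones: Optional[ZoneBoundaries] = None,
    reference: Literal["daytime", "24h"] = "daytime",
    reference_threshold: ThresholdPair = OUT_OF_OFFICE_HT_THRESHOLD,
) -> CascadeOutcome:
    """Run one subject through a cascade strategy."""

    def by_reference(office_zone=None, home_zone=None) -> CascadeOutcome:
        ref = _require(_reference_bp(subject, reference), subject.subject_id, strategy, "ambulatory")
        ht = is_hypertensive(ref, reference_threshold)
        return CascadeOutcome(
            subject_id=subject.subject_id,
            diagnosis="hypertensive" if ht else "normotensive",
            terminal_stage="ambulatory",
            office_zone=office_zone,
            home_zone=home_zone,
        )

    def by_home(office_zone=None) -> CascadeOutcome:
        if home_zones is None:
            raise ValueError(f"strategy {strategy.value} needs home zone boundaries")
        home = _require(subject.home, subject.subject_id, strategy, "home")
        zone = assign_zone(home, home_zones)
        if zone == Zone.INTERMEDIATE:
            return by_reference(office_zone=office_zone, home_zone=zone)
        return CascadeOutcome(
            subject_id=subject.subject_id,
            diagnosis="hypertensive" if zone == Zone.HYPERTENSION else "normotensive",
            terminal_stage="home",
            office_zone=office_zone,
            home_zone=zone,
        )

    if strategy in (Strategy.OBP_ABP, Strategy.OBP_HBP_ABP):
        if office_zones is None:
            raise ValueError(f"strategy {strategy.value} needs office zone boundaries")
        office = _require(subject.office, subject.subject_id, strategy, "office")
        zone = assign_zone(office, office_zones)
        if zone != Zone.INTERMEDIATE:
            return CascadeOutcome(
                subject_id=subject.subject_id,
                diagnosis="hypertensive" if zone == Zone.HYPERTENSION else "normotensive",
                terminal_stage="office",
                office_zone=zone,
            )
        if strategy == Strategy.OBP_ABP:
            return by_reference(office_zone=zone)
        return by_home(office_zone=zone)

    if strategy == Strategy.HBP_ABP:
        return by_home()

    raise ValueError(f"unknown strategy {strategy!r}")


def tabulate_zone_phenotypes(
    cohort: Sequence[AggregatedSubject],
    boundaries: ZoneBoundaries,
    arm: Literal["office", "home"],
    reference: Literal["daytime", "24h"] = "daytime",
    reference_threshold: ThresholdPair = OUT_OF_OFFICE_HT_THRESHOLD,
) -> ZonePhenotypeTable:
    """Cross-tabulate phenotype (by the arm's own threshold) against zone."""
    counts = {p.value: [0, 0, 0] for p in PHENOTYPE_ORDER}
    threshold = arm_threshold(arm)
    for s in cohort:
        arm_bp = s.office if arm == "office" else s.home
        ref_bp = _reference_bp(s, reference)
        if arm_bp is None or ref_bp is None:
            raise MissingStageError(
                f"subject {s.subject_id}: tabulation needs valid {arm} and {reference} BP"
            )
        phenotype = classify_phenotype(
            is_hypertensive(arm_bp, threshold), is_hypertensive(ref_bp, reference_threshold)
        )
        zone = assign_zone(arm_bp, boundaries)
        counts[phenotype.value][ZONE_ORDER.index(zone)] += 1
    return ZonePhenotypeTable.from_dict(counts, arm=arm)


def evaluate_from_zone_table(table: ZonePhenotypeTable) -> ConfusionCounts:
    """Cascade confusion counts from a phenotype-by-zone table.

    Reference-positives are MH + SH; hypertension-zone subjects test
    positive, normotension-zone subjects negative, and intermediate-zone
    subjects are resolved by the reference itself (always correctly).
    Hence FP = white-coat counts in the hypertension zone (plus any NT
    there) and FN = masked counts in the normotension zone (plus any SH
    there).
    """
    nt_zone, ht_zone = Zone.NORMOTENSION, Zone.HYPERTENSION
    positives = sum(table.cell(p, z) for p in (Phenotype.MH, Phenotype.SH) for z in ZONE_ORDER)
    negatives = table.n_total - positives
    fn = table.cell(Phenotype.MH, nt_zone) + table.cell(Phenotype.SH, nt_zone)
    fp = table.cell(Phenotype.WH, ht_zone) + table.cell(Phenotype.NT, ht_zone)
    return ConfusionCounts(tp=positives - fn, fp=fp, fn=fn, tn=negatives - fp)


def evaluate_threshold_alone(
    table: ZonePhenotypeTable, exclude_intermediate: bool = False
) -> ConfusionCounts:
    """Confusion counts of the arm's plain diagnostic threshold.

    The phenotype columns already encode test positivity (WH and SH are
    test-positive, NT and MH test-negative).  With
    ``exclude_intermediate`` the intermediate-zone subjects are dropped
    before counting, emulating a rule-in/rule-out-only analysis.
    """
    zones = [Zone.NORMOTENSION, Zone.HYPERTENSION] if exclude_intermediate else ZONE_ORDER

    def total(p: Phenotype) -> int:
        return sum(table.cell(p, z) for z in zones)

    tp, fp, fn, tn = total(Phenotype.SH), total(Phenotype.WH), total(Phenotype.MH), total(Phenotype.NT)
    if exclude_intermediate and (tp + fn == 0 or fp + tn == 0):
        raise ValueError(
            "excluding the intermediate zone leaves an empty reference class "
            f"(positives {tp + fn}, negatives {fp + tn})"
        )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_strategy(
    cohort: Sequence[AggregatedSubject],
    strategy: Strategy,
    office_zones: Optional[ZoneBoundaries] = None,
    home_zones: Optional[ZoneBoundaries] = None,
    reference: Literal["daytime", "24h"] = "daytime",
    reference_threshold: ThresholdPair = OUT_OF_OFFICE_HT_THRESHOLD,
) -> ConfusionCounts:
    """Subject-level confusion counts of a strategy against the reference.

    For the single-arm strategies the result is cross-checked against
    the count-level evaluation of the corresponding phenotype-by-zone
    table; a mismatch would indicate an internal inconsistency.
    """
    tp = fp = fn = tn = 0
    for s in cohort:
        outcome = diagnose(s, strategy, office_zones, home_zones, reference, reference_threshold)
        ref = _require(_reference_bp(s, reference), s.subject_id, strategy, "ambulatory reference")
        truth = is_hypertensive(ref, reference_threshold)
        if outcome.hypertensive and truth:
            tp += 1
        elif outcome.hypertensive:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)

    if strategy in (Strategy.OBP_ABP, Strategy.HBP_ABP) and cohort:
        arm = "office" if strategy == Strategy.OBP_ABP else "home"
        boundaries = office_zones if arm == "office" else home_zones
        table = tabulate_zone_phenotypes(cohort, boundaries, arm, reference, reference_threshold)
        assert evaluate_from_zone_table(table) == counts, (
            "subject-level and count-level cascade evaluations disagree"
        )
    return counts
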