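"""Hypertension thresholds, phenotypes, and ROC-derived BP zones.

The triage algorithm splits office and home BP into three zones:

* **normotension zone** — below both lower cut-offs; hypertension ruled
  out without ambulatory monitoring;
* **hypertension zone** — at or above either upper cut-off; hypertension
  ruled in without ambulatory monitoring;
* **intermediate zone** — everything between, where daytime ambulatory
  BP (the reference standard, hypertensive at >= 135/85 mmHg) must
  arbitrate.

The lower boundary of the intermediate zone is the largest observed
cut-off retaining 95 % sensitivity for daytime ambulatory hypertension,
the upper boundary the smallest observed cut-off reaching 95 %
specificity; both are then rounded to the nearest multiple of 5 mmHg for
clinical convenience.  Systolic and diastolic cut-offs are derived
independently against the same binary reference truth, and zone
membership combines them with worst-component logic (either component
can rule in; both must clear the lower bound to rule out), matching the
"and/or" convention of the 140/90-style diagnostic thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np

from .aggregation import AggregatedSubject, BPPair

__all__ = [
    "Zone",
    "Phenotype",
    "ThresholdPair",
    "ZoneBoundaries",
    "RawCutoffs",
    "OFFICE_HT_THRESHOLD",
    "OUT_OF_OFFICE_HT_THRESHOLD",
    "is_hypertensive",
    "classify_phenotype",
    "roc_cutoff_at_sensitivity",
    "roc_cutoff_at_specificity",
    "round_to_multiple_of_5",
    "derive_raw_cutoffs",
    "derive_zone_boundaries",
    "assign_zone",
]


class Zone(str, Enum):
    NORMOTENSION = "normotension"
    INTERMEDIATE = "intermediate"
    HYPERTENSION = "hypertension"


class Phenotype(str, Enum):
    """Concordance phenotype of a screening test against the reference standard."""

    NT = "NT"  # normotension: both negative
    WH = "WH"  # white-coat hypertension: test positive, reference negative
    MH = "MH"  # masked hypertension: test negative, reference positive
    SH = "SH"  # sustained hypertension: both positive


@dataclass(frozen=True)
class ThresholdPair:
    """An SBP/DBP diagnostic threshold in mmHg (positive if either is met)."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError(f"threshold must satisfy sbp > dbp > 0, got {self.sbp}/{self.dbp}")


#: Office hypertension: >= 140/90 mmHg.
OFFICE_HT_THRESHOLD = ThresholdPair(140.0, 90.0)
#: Home and daytime-ambulatory hypertension: >= 135/85 mmHg.
OUT_OF_OFFICE_HT_THRESHOLD = ThresholdPair(135.0, 85.0)


@dataclass(frozen=True)
class ZoneBoundaries:
    """Lower/upper SBP and DBP cut-offs bounding the intermediate zone."""

    lower: ThresholdPair
    upper: ThresholdPair
    modality: Literal["office", "home"]

    def __post_init__(self) -> None:
        if not (self.lower.sbp < self.upper.sbp and self.lower.dbp < self.upper.dbp):
            raise ValueError(
                f"degenerate zones: lower {self.lower.sbp}/{self.lower.dbp} "
                f"not below upper {self.upper.sbp}/{self.upper.dbp}"
            )
        for v in (self.lower.sbp, self.lower.dbp, self.upper.sbp, self.upper.dbp):
            if v % 5 != 0:
                raise ValueError(f"zone cut-offs must be multiples of 5 mmHg, got {v}")


@dataclass(frozen=True)
class RawCutoffs:
    """Unrounded ROC cut-offs (mmHg) for one modality."""

    lower_sbp: float
    lower_dbp: float
    upper_sbp: float
    upper_dbp: float


def is_hypertensive(bp: BPPair, threshold: ThresholdPair) -> bool:
    """Either component at or above its threshold diagnoses hypertension."""
    return bp.sbp >= threshold.sbp or bp.dbp >= threshold.dbp


def classify_phenotype(screen_ht: bool, reference_ht: bool) -> Phenotype:
    if screen_ht:
        return Phenotype.SH if reference_ht else Phenotype.WH
    return Phenotype.MH if reference_ht else Phenotype.NT


def _check_roc_inputs(values: Sequence[float], truth: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("values and truth must be aligned 1-D sequences")
    if not (t.any() and (~t).any()):
        raise ValueError("both truth classes must be present for ROC cut-off search")
    return v, t


def roc_cutoff_at_sensitivity(
    values: Sequence[float], truth: Sequence[bool], target: float = 0.95
) -> float:
    """Largest observed cut-off whose sensitivity still reaches ``target``.

    Candidate cut-offs are the observed values themselves; a subject is
    test-positive when its value is >= the cut-off.
    """
    v, t = _check_roc_inputs(values, truth)
    pos = np.sort(v[t])
    candidates = np.unique(v)
    # sensitivity(c) = #{pos >= c} / #pos
    sens = (len(pos) - np.searchsorted(pos, candidates, side="left")) / len(pos)
    ok = candidates[sens >= target]
    if ok.size == 0:
        raise ValueError(f"no observed cut-off reaches sensitivity {target}")
    return float(ok.max())


def roc_cutoff_at_specificity(
    values: Sequence[float], truth: Sequence[bool], target: float = 0.95
) -> float:
    """Smallest observed cut-off whose specificity reaches ``target``.

    Specificity of cut-off ``c`` is the fraction of reference-negative
    subjects with value strictly below ``c`` (they test negative).
    """
    v, t = _check_roc_inputs(values, truth)
    neg = np.sort(v[~t])
    candidates = np.unique(v)
    spec = np.searchsorted(neg, candidates, side="left") / len(neg)
    ok = candidates[spec >= target]
    if ok.size == 0:
        raise ValueError(f"no observed cut-off reaches specificity {target}")
    return float(ok.min())


def round_to_multiple_of_5(x: float) -> float:
    """Nearest multiple of 5 mmHg; exact midpoints round up."""
    if x <= 0:
        raise ValueError("blood pressure cut-offs are positive")
    return float(math.floor(x / 5.0 + 0.5) * 5)


def _modality_pairs(
    cohort: Sequence[AggregatedSubject],
    modality: Literal["office", "home"],
    reference: Literal["daytime", "24h"],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sbp, dbp, ref = [], [], []
    for s in cohort:
        test_bp = s.office if modality == "office" else s.home
        ref_bp = s.daytime_abp if reference == "daytime" else s.abp_24h
        if test_bp is None or ref_bp is None:
            continue
        sbp.append(test_bp.sbp)
        dbp.append(test_bp.dbp)
        ref.append(ref_bp)
    return np.array(sbp), np.array(dbp), np.array(ref, dtype=object)


def derive_raw_cutoffs(
    cohort: Sequence[AggregatedSubject],
    modality: Literal["office", "home"] = "office",
    reference: Literal["daytime", "24h"] = "daytime",
    reference_threshold: ThresholdPair = OUT_OF_OFFICE_HT_THRESHOLD,
    target_sensitivity: float = 0.95,
    target_specificity: float = 0.95,
) -> RawCutoffs:
    """Unrounded ROC cut-offs for one modality against reference hypertension."""
    sbp, dbp, ref = _modality_pairs(cohort, modality, reference)
    if sbp.size == 0:
        raise ValueError(f"no subjects with valid {modality} and {reference} reference BP")
    truth = np.array([is_hypertensive(r, reference_threshold) for r in ref])
    return RawCutoffs(
        lower_sbp=roc_cutoff_at_sensitivity(sbp, truth, target_sensitivity),
        lower_dbp=roc_cutoff_at_sensitivity(dbp, truth, target_sensitivity),
        upper_sbp=roc_cutoff_at_specificity(sbp, truth, target_specificity),
        upper_dbp=roc_cutoff_at_specificity(dbp, truth, target_specificity),
    )


def derive_zone_boundaries(
    cohort: Sequence[AggregatedSubject],
    modality: Literal["office", "home"] = "office",
    reference: Literal["daytime", "24h"] = "daytime",
    reference_threshold: ThresholdPair = OUT_OF_OFFICE_HT_THRESHOLD,
    target_sensitivity: float = 0.95,
    target_specificity: float = 0.95,
) -> ZoneBoundaries:
    """Rounded intermediate-zone boundaries for one modality.

    Raises when rounding collapses the zone (lower >= upper), reporting
    the raw cut-offs so the degenerate derivation can be inspected.
    """
    raw = derive_raw_cutoffs(
        cohort,
        modality,
        reference,
        reference_threshold,
        target_sensitivity,
        target_specificity,
    )
    lower = (round_to_multiple_of_5(raw.lower_sbp), round_to_multiple_of_5(raw.lower_dbp))
    upper = (round_to_multiple_of_5(raw.upper_sbp), round_to_multiple_of_5(raw.upper_dbp))
    if lower[0] >= upper[0] or lower[1] >= upper[1]:
        raise ValueError(
            f"degenerate {modality} zones after rounding: lower {lower} >= upper {upper} "
            f"(raw cut-offs {raw})"
        )
    return ZoneBoundaries(
        lower=ThresholdPair(*lower), upper=ThresholdPair(*upper), modality=modality
    )


def assign_zone(bp: BPPair, boundaries: ZoneBoundaries) -> Zone:
    """Worst-component zone: either component can rule in, both must rule out."""
    if bp.sbp >= boundaries.upper.sbp or bp.dbp >= boundaries.upper.dbp:
        return Zone.HYPERTENSION
    if bp.sbp < boundaries.lower.sbp and bp.dbp < boundaries.lower.dbp:
        return Zone.NORMOTENSION
    return Zone.INTERMEDIATE
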