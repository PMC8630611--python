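"""Diagnostic accuracy metrics with exact binomial confidence intervals.

Every metric of a 2x2 confusion table (sensitivity, specificity, PPV,
NPV, accuracy) is a binomial proportion and is reported with an exact
central Clopper-Pearson interval.  The AUC of a single operating point
is the trapezoidal area (sensitivity + specificity) / 2; its interval
uses the Hanley-McNeil standard error and is labelled as such, since a
one-point ROC curve admits no exact interval.

Two estimates are called statistically different when their confidence
intervals (closed) do not overlap — a deliberately conservative rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ProportionCI",
    "DiagnosticMetrics",
    "clopper_pearson",
    "auc_single_point",
    "compute_metrics",
    "ci_overlap",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Non-negative TP/FP/FN/TN counts against a binary reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError(f"confusion counts must be non-negative integers, got {counts}")
        if sum(counts) < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with a two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValueError(
                f"interval must satisfy 0 <= lower <= estimate <= upper <= 1, "
                f"got {self.lower}, {self.estimate}, {self.upper}"
            )

    @property
    def percent(self) -> tuple[float, float, float]:
        """(estimate, lower, upper) on the percentage scale."""
        return 100 * self.estimate, 100 * self.lower, 100 * self.upper


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The metric panel of one diagnostic strategy.

    A metric whose denominator is zero is ``None`` (undefined) rather
    than an error, so degenerate tables still yield the rest of the
    panel.
    """

    counts: ConfusionCounts
    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    accuracy: ProportionCI
    auc: Optional[ProportionCI]
    level: float = 0.95


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Exact central binomial confidence interval.

    The bounds are beta-distribution quantiles:
    ``lower = Beta(k, n-k+1).ppf(alpha/2)`` (0 when k = 0) and
    ``upper = Beta(k+1, n-k).ppf(1-alpha/2)`` (1 when k = n).
    """
    k, n = int(successes), int(trials)
    if not (0 <= k <= n and n >= 1):
        raise ValueError(f"need 0 <= successes <= trials with trials >= 1, got {successes}/{trials}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(estimate=k / n, lower=lower, upper=upper, level=level)


def auc_single_point(counts: ConfusionCounts, level: float = 0.95) -> Optional[ProportionCI]:
    """Single-operating-point AUC = (sensitivity + specificity) / 2.

    The confidence interval uses the Hanley-McNeil standard error for an
    AUC estimated from ``positives`` x ``negatives`` comparisons, normal
    on the AUC scale and clipped to [0, 1].
    """
    n_pos, n_neg = counts.positives, counts.negatives
    if n_pos == 0 or n_neg == 0:
        return None
    auc = 0.5 * (counts.tp / n_pos + counts.tn / n_neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc) + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(0.5 + level / 2))
    lower = min(max(auc - z * se, 0.0), auc)
    upper = max(min(auc + z * se, 1.0), auc)
    return ProportionCI(estimate=auc, lower=lower, upper=upper, level=level, method="hanley-mcneil")


def _ratio_ci(successes: int, trials: int, level: float) -> Optional[ProportionCI]:
    return clopper_pearson(successes, trials, level) if trials >= 1 else None


def compute_metrics(counts: ConfusionCounts, level: float = 0.95) -> DiagnosticMetrics:
    """Full metric panel for one confusion table."""
    return DiagnosticMetrics(
        counts=counts,
        sensitivity=_ratio_ci(counts.tp, counts.tp + counts.fn, level),
        specificity=_ratio_ci(counts.tn, counts.tn + counts.fp, level),
        ppv=_ratio_ci(counts.tp, counts.tp + counts.fp, level),
        npv=_ratio_ci(counts.tn, counts.tn + counts.fn, level),
        accuracy=clopper_pearson(counts.tp + counts.tn, counts.total, level),
        auc=auc_single_point(counts, level),
        level=level,
    )


def ci_overlap(a: ProportionCI, b: ProportionCI) -> bool:
    """Whether two closed confidence intervals intersect.

    Touching endpoints count as overlap; non-overlap is read as a
    statistically significant difference.
    """
    if a.level != b.level:
        raise ValueError(f"cannot compare intervals at levels {a.level} and {b.level}")
    return a.lower <= b.upper and b.lower <= a.upper
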