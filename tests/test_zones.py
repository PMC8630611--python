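"""Thresholds, ROC cut-off search, rounding, and zone assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bptriage.aggregation import AggregatedSubject, BPPair
from bptriage.zones import (
    OUT_OF_OFFICE_HT_THRESHOLD,
    Phenotype,
    ThresholdPair,
    Zone,
    ZoneBoundaries,
    assign_zone,
    classify_phenotype,
    derive_raw_cutoffs,
    derive_zone_boundaries,
    is_hypertensive,
    roc_cutoff_at_sensitivity,
    roc_cutoff_at_specificity,
    round_to_multiple_of_5,
)


class TestHypertensionRule:
    @pytest.mark.parametrize(
        "bp,expected",
        [
            ((134, 86), True),  # DBP alone qualifies
            ((134.9, 84.9), False),
            ((135, 84), True),  # boundary inclusive on SBP
            ((135, 85), True),
        ],
    )
    def test_or_rule_against_135_85(self, bp, expected):
        assert is_hypertensive(BPPair(*bp), OUT_OF_OFFICE_HT_THRESHOLD) is expected

    @pytest.mark.parametrize(
        "screen,ref,expected",
        [
            (False, False, Phenotype.NT),
            (True, False, Phenotype.WH),
            (False, True, Phenotype.MH),
            (True, True, Phenotype.SH),
        ],
    )
    def test_phenotype_mapping(self, screen, ref, expected):
        assert classify_phenotype(screen, ref) is expected


def brute_force_cutoffs(values, truth, target=0.95):
    """Exhaustive scan over observed candidate cut-offs (independent oracle)."""
    values = np.asarray(values, float)
    truth = np.asarray(truth, bool)
    sens_ok, spec_ok = [], []
    for c in np.unique(values):
        sens = np.mean(values[truth] >= c)
        spec = np.mean(values[~truth] < c)
        if sens >= target:
            sens_ok.append(c)
        if spec >= target:
            spec_ok.append(c)
    return (max(sens_ok) if sens_ok else None, min(spec_ok) if spec_ok else None)


class TestRocCutoffs:
    def test_sensitivity_cutoff_small_example(self):
        values = [140, 150, 160, 120, 125]
        truth = [True, True, True, False, False]
        assert roc_cutoff_at_sensitivity(values, truth) == 140

    def test_all_positives_equal(self):
        values = [150, 150, 150, 100]
        truth = [True, True, True, False]
        assert roc_cutoff_at_sensitivity(values, truth) == 150

    def test_sensitivity_95_with_20_positives(self):
        # 19/20 >= 0.95 at 132; 18/20 < 0.95 at 133
        values = list(range(131, 151)) + [100]
        truth = [True] * 20 + [False]
        assert roc_cutoff_at_sensitivity(values, truth, 0.95) == 132

    def test_specificity_cutoff_small_example(self):
        values = [120, 125, 130, 150]
        truth = [False, False, False, True]
        assert roc_cutoff_at_specificity(values, truth) == 150

    def test_specificity_95_with_20_negatives(self):
        values = list(range(120, 140)) + [160]
        truth = [False] * 20 + [True]
        assert roc_cutoff_at_specificity(values, truth, 0.95) == 139

    def test_single_negative(self):
        assert roc_cutoff_at_specificity([100, 150], [False, True]) == 150

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both truth classes"):
            roc_cutoff_at_sensitivity([1, 2], [True, True])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        truth = np.zeros(n, bool)
        truth[: max(2, n // 3)] = True
        rng.shuffle(truth)
        values = np.round(rng.normal(135 + 10 * truth, 12), 1)
        target = float(rng.choice([0.8, 0.9, 0.95]))
        bf_sens, bf_spec = brute_force_cutoffs(values, truth, target)
        assert roc_cutoff_at_sensitivity(values, truth, target) == bf_sens
        if bf_spec is not None:
            assert roc_cutoff_at_specificity(values, truth, target) == bf_spec

    def test_cutoffs_meet_their_targets_by_construction(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            truth = rng.random(n) < 0.6
            if truth.all() or not truth.any():
                continue
            values = rng.normal(135 + 8 * truth, 10)
            lo = roc_cutoff_at_sensitivity(values, truth)
            hi = roc_cutoff_at_specificity(values, truth)
            assert np.mean(values[truth] >= lo) >= 0.95
            assert np.mean(values[~truth] < hi) >= 0.95


class TestRounding:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (130.2, 130),
            (146.1, 145),
            (81.1, 80),
            (96.2, 95),
            (120.5, 120),
            (78.0, 80),
            (143.7, 145),
            (94.0, 95),
            (127.5, 130),  # exact midpoint rounds up
        ],
    )
    def test_nearest_multiple_of_5(self, raw, expected):
        assert round_to_multiple_of_5(raw) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            round_to_multiple_of_5(0)


def _subject(i, office, daytime, home=None):
    return AggregatedSubject(
        subject_id=f"T{i}",
        office=BPPair(*office),
        home=BPPair(*home) if home else None,
        daytime_abp=BPPair(*daytime),
        abp_24h=BPPair(*daytime),
        home_valid=home is not None,
        abp_valid=True,
        index_arm="right",
    )


class TestDeriveZones:
    def test_perfect_test_collapses_the_intermediate_zone(self):
        """When the screening value *is* the reference value, the 95%-spec
        cut-off sits at or below the diagnostic threshold and the 95%-sens
        cut-off at or above it: a perfect test needs no confirmatory zone,
        and the rounded derivation reports it as degenerate."""
        rng = np.random.default_rng(0)
        cohort = []
        for i in range(80):
            sbp = float(rng.uniform(110, 165))
            dbp = 0.5 * sbp + 10.0  # monotone in SBP, never reaches 85 before SBP reaches 135
            cohort.append(_subject(i, (sbp, dbp), (sbp, dbp)))
        raw = derive_raw_cutoffs(cohort, "office")
        assert raw.upper_sbp <= 135 <= raw.lower_sbp
        assert raw.upper_dbp <= raw.lower_dbp
        with pytest.raises(ValueError, match="degenerate"):
            derive_zone_boundaries(cohort, "office")

    def test_matches_brute_force_on_handmade_cohort(self):
        rng = np.random.default_rng(42)
        cohort = []
        for i in range(40):
            day = (float(rng.normal(137, 13)), float(rng.normal(90, 11)))
            office = (day[0] + float(rng.normal(3, 7)), day[1] + float(rng.normal(2, 5)))
            cohort.append(_subject(i, office, day))
        truth = np.array(
            [is_hypertensive(s.daytime_abp, OUT_OF_OFFICE_HT_THRESHOLD) for s in cohort]
        )
        sbps = np.array([s.office.sbp for s in cohort])
        raw = derive_raw_cutoffs(cohort, "office")
        bf_lo, bf_hi = brute_force_cutoffs(sbps, truth, 0.95)
        assert raw.lower_sbp == bf_lo
        assert raw.upper_sbp == bf_hi

    def test_development_cohort_recovers_published_office_zones(self, dev_cohort):
        zones = derive_zone_boundaries(dev_cohort.cohort, "office")
        assert abs(zones.lower.sbp - 130) <= 5
        assert abs(zones.lower.dbp - 80) <= 5
        assert abs(zones.upper.sbp - 145) <= 5
        assert abs(zones.upper.dbp - 95) <= 5

    def test_derivation_cohort_meets_sensitivity_and_specificity_targets(self, dev_cohort):
        for modality in ("office", "home"):
            raw = derive_raw_cutoffs(dev_cohort.cohort, modality)
            values = np.array(
                [
                    (s.office if modality == "office" else s.home).sbp
                    for s in dev_cohort.cohort
                ]
            )
            truth = np.array(
                [
                    is_hypertensive(s.daytime_abp, OUT_OF_OFFICE_HT_THRESHOLD)
                    for s in dev_cohort.cohort
                ]
            )
            assert np.mean(values[truth] >= raw.lower_sbp) >= 0.95
            assert np.mean(values[~truth] < raw.upper_sbp) >= 0.95


OFFICE_ZONES = ZoneBoundaries(ThresholdPair(130, 80), ThresholdPair(145, 95), "office")


class TestAssignZone:
    @pytest.mark.parametrize(
        "bp,zone",
        [
            ((138, 88), Zone.INTERMEDIATE),
            ((125, 96), Zone.HYPERTENSION),  # DBP alone rules in
            ((129, 79), Zone.NORMOTENSION),
            ((129, 80), Zone.INTERMEDIATE),  # DBP at lower bound blocks rule-out
            ((145, 70), Zone.HYPERTENSION),
        ],
    )
    def test_worst_component_logic(self, bp, zone):
        assert assign_zone(BPPair(*bp), OFFICE_ZONES) is zone

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(60, 250, allow_nan=False),
        st.floats(40, 190, allow_nan=False),
    )
    def test_partition_and_monotonicity(self, sbp, dbp):
        order = [Zone.NORMOTENSION, Zone.INTERMEDIATE, Zone.HYPERTENSION]
        z = assign_zone(BPPair(sbp, dbp), OFFICE_ZONES)
        assert z in order
        # raising either component never lowers the zone
        for d_sbp, d_dbp in ((7.0, 0.0), (0.0, 7.0), (12.0, 12.0)):
            z_up = assign_zone(BPPair(sbp + d_sbp, dbp + d_dbp), OFFICE_ZONES)
            assert order.index(z_up) >= order.index(z)

    def test_hypertension_rule_matches_upper_bound_zone(self):
        """An upper bound equal to a diagnostic threshold reproduces its or-rule."""
        t = ThresholdPair(140, 90)
        zones = ZoneBoundaries(ThresholdPair(120, 75), t, "office")
        rng = np.random.default_rng(1)
        for _ in range(200):
            bp = BPPair(float(rng.uniform(100, 180)), float(rng.uniform(60, 120)))
            assert (assign_zone(bp, zones) is Zone.HYPERTENSION) == is_hypertensive(bp, t)

    def test_degenerate_boundaries_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ZoneBoundaries(ThresholdPair(145, 95), ThresholdPair(130, 95), "office")
        with pytest.raises(ValueError, match="multiples of 5"):
            ZoneBoundaries(ThresholdPair(131, 80), ThresholdPair(145, 95), "office")
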