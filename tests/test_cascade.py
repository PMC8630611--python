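"""Cascade strategies, phenotype-by-zone tables, and count-level evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bptriage.aggregation import AggregatedSubject, BPPair
from bptriage.cascade import (
    MissingStageError,
    Strategy,
    ZonePhenotypeTable,
    diagnose,
    evaluate_from_zone_table,
    evaluate_strategy,
    evaluate_threshold_alone,
    tabulate_zone_phenotypes,
)
from bptriage.metrics import ConfusionCounts
from bptriage.reference_tables import HOME_ZONES, OFFICE_ZONES, zone_table
from bptriage.zones import Phenotype, Zone


def _subject(i, office, daytime, home=None):
    return AggregatedSubject(
        subject_id=f"C{i}",
        office=BPPair(*office),
        home=BPPair(*home) if home else None,
        daytime_abp=BPPair(*daytime),
        abp_24h=BPPair(*daytime),
        home_valid=home is not None,
        abp_valid=True,
        index_arm="right",
    )


class TestDiagnose:
    def test_hypertension_zone_decides_without_ambulatory(self):
        s = _subject(1, (150, 96), (120, 70))
        out = diagnose(s, Strategy.OBP_ABP, office_zones=OFFICE_ZONES)
        assert out.diagnosis == "hypertensive"
        assert out.terminal_stage == "office"
        assert out.office_zone is Zone.HYPERTENSION

    def test_intermediate_zone_resolved_by_reference(self):
        s = _subject(2, (138, 88), (138, 86))
        out = diagnose(s, Strategy.OBP_ABP, office_zones=OFFICE_ZONES)
        assert out.diagnosis == "hypertensive"
        assert out.terminal_stage == "ambulatory"

    def test_office_intermediate_falls_through_to_home_zone(self):
        s = _subject(3, (138, 88), (140, 90), home=(118, 78))
        out = diagnose(s, Strategy.OBP_HBP_ABP, office_zones=OFFICE_ZONES, home_zones=HOME_ZONES)
        assert out.diagnosis == "normotensive"
        assert out.terminal_stage == "home"
        assert out.home_zone is Zone.NORMOTENSION

    def test_home_first_strategy_ignores_office(self):
        s = _subject(4, (170, 110), (120, 70), home=(115, 75))
        out = diagnose(s, Strategy.HBP_ABP, home_zones=HOME_ZONES)
        assert out.diagnosis == "normotensive"
        assert out.terminal_stage == "home"

    def test_missing_home_measurement_names_subject_strategy_stage(self):
        s = _subject(5, (138, 88), (140, 90))  # no home data
        with pytest.raises(MissingStageError, match="C5.*OBP-HBP-ABP.*home"):
            diagnose(s, Strategy.OBP_HBP_ABP, office_zones=OFFICE_ZONES, home_zones=HOME_ZONES)

    def test_obp_hbp_abp_agrees_with_obp_abp_outside_intermediate(self, dev_cohort):
        for s in dev_cohort.cohort[:300]:
            a = diagnose(s, Strategy.OBP_ABP, OFFICE_ZONES, HOME_ZONES)
            if a.office_zone is not Zone.INTERMEDIATE:
                b = diagnose(s, Strategy.OBP_HBP_ABP, OFFICE_ZONES, HOME_ZONES)
                assert a.diagnosis == b.diagnosis
                assert a.terminal_stage == b.terminal_stage == "office"


class TestTabulate:
    def test_single_sustained_hypertensive(self):
        table = tabulate_zone_phenotypes([_subject(1, (150, 96), (140, 90))], OFFICE_ZONES, "office")
        assert table.cell(Phenotype.SH, Zone.HYPERTENSION) == 1
        assert table.n_total == 1

    def test_noise_free_table_equals_latent_tabulation(self, noise_free_cohort):
        from bptriage.aggregation import aggregate_cohort

        params, subjects, profiles = noise_free_cohort
        aggs = aggregate_cohort(subjects)
        table = tabulate_zone_phenotypes(aggs, OFFICE_ZONES, "office")
        latent_subjects = [
            _subject(i, (p.true_bp[0], p.true_bp[1]), (p.true_bp[4], p.true_bp[5]))
            for i, p in enumerate(profiles)
        ]
        latent_table = tabulate_zone_phenotypes(latent_subjects, OFFICE_ZONES, "office")
        assert table.counts.equals(latent_table.counts)

    def test_development_preset_places_discordant_phenotypes_in_intermediate(self, dev_cohort):
        table = tabulate_zone_phenotypes(dev_cohort.cohort, OFFICE_ZONES, "office")
        wh = table.counts.loc["WH"]
        mh = table.counts.loc["MH"]
        assert (wh["intermediate"] + mh["intermediate"]) / (wh.sum() + mh.sum()) > 0.5


class TestCountLevelEvaluation:
    def test_development_office_panel_counts(self):
        c = evaluate_from_zone_table(zone_table("development", "office"))
        assert c == ConfusionCounts(tp=186, fp=7, fn=2, tn=61)

    def test_development_home_panel_counts(self):
        c = evaluate_from_zone_table(zone_table("development", "home"))
        assert c == ConfusionCounts(tp=179, fp=4, fn=9, tn=64)

    def test_threshold_alone_development_office(self):
        t = zone_table("development", "office")
        assert evaluate_threshold_alone(t) == ConfusionCounts(tp=146, fp=20, fn=42, tn=48)
        assert evaluate_threshold_alone(t, exclude_intermediate=True) == ConfusionCounts(
            tp=108, fp=7, fn=2, tn=14
        )

    def test_single_cell_table(self):
        counts = {"NT": (0, 0, 0), "WH": (0, 0, 0), "MH": (0, 0, 0), "SH": (0, 0, 1)}
        t = ZonePhenotypeTable.from_dict(counts, arm="office")
        assert evaluate_threshold_alone(t) == ConfusionCounts(tp=1, fp=0, fn=0, tn=0)
        assert evaluate_from_zone_table(t) == ConfusionCounts(tp=1, fp=0, fn=0, tn=0)

    def test_empty_intermediate_cascade_equals_threshold_alone(self):
        # zone dichotomy consistent with the phenotype dichotomy, intermediate empty
        counts = {"NT": (30, 0, 0), "WH": (0, 0, 10), "MH": (12, 0, 0), "SH": (0, 0, 48)}
        t = ZonePhenotypeTable.from_dict(counts, arm="office")
        assert evaluate_from_zone_table(t) == evaluate_threshold_alone(t)

    def test_exclusion_emptying_a_class_rejected(self):
        counts = {"NT": (0, 5, 0), "WH": (0, 3, 0), "MH": (2, 0, 0), "SH": (0, 0, 7)}
        t = ZonePhenotypeTable.from_dict(counts, arm="office")
        with pytest.raises(ValueError, match="empty reference class"):
            evaluate_threshold_alone(t, exclude_intermediate=True)


@st.composite
def zone_tables(draw):
    counts = {
        p: tuple(int(draw(st.integers(0, 60))) for _ in range(3)) for p in ("NT", "WH", "MH", "SH")
    }
    if sum(sum(v) for v in counts.values()) == 0:
        counts["SH"] = (0, 0, 1)
    return ZonePhenotypeTable.from_dict(counts, arm="office")


class TestCascadeIdentities:
    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(zone_tables())
    def test_error_decomposition_holds_exactly(self, table):
        """Cascade errors are exactly the discordant phenotypes stranded in a
        terminal zone: WH (or NT) ruled in, MH (or SH) ruled out."""
        c = evaluate_from_zone_table(table)
        errors = (
            table.cell(Phenotype.WH, Zone.HYPERTENSION)
            + table.cell(Phenotype.NT, Zone.HYPERTENSION)
            + table.cell(Phenotype.MH, Zone.NORMOTENSION)
            + table.cell(Phenotype.SH, Zone.NORMOTENSION)
        )
        assert c.fp + c.fn == errors
        assert (c.tp + c.tn) == table.n_total - errors

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(zone_tables())
    def test_cascade_dominates_threshold_alone_when_zones_bracket_threshold(self, table):
        """When the arm's threshold lies inside the zones, WH/SH cannot sit in
        the normotension zone nor NT/MH in the hypertension zone; then the
        cascade's sensitivity and specificity dominate the plain threshold's."""
        cleaned = {
            "NT": (table.cell(Phenotype.NT, Zone.NORMOTENSION), table.cell(Phenotype.NT, Zone.INTERMEDIATE), 0),
            "MH": (table.cell(Phenotype.MH, Zone.NORMOTENSION), table.cell(Phenotype.MH, Zone.INTERMEDIATE), 0),
            "WH": (0, table.cell(Phenotype.WH, Zone.INTERMEDIATE), table.cell(Phenotype.WH, Zone.HYPERTENSION)),
            "SH": (0, table.cell(Phenotype.SH, Zone.INTERMEDIATE), table.cell(Phenotype.SH, Zone.HYPERTENSION)),
        }
        if sum(sum(v) for v in cleaned.values()) == 0:
            cleaned["SH"] = (0, 0, 1)
        t = ZonePhenotypeTable.from_dict(cleaned, arm="office")
        cascade = evaluate_from_zone_table(t)
        alone = evaluate_threshold_alone(t)
        if cascade.positives:
            assert cascade.tp / cascade.positives >= alone.tp / alone.positives
        if cascade.negatives:
            assert cascade.tn / cascade.negatives >= alone.tn / alone.negatives

    def test_subject_level_equals_count_level_on_synthetic_cohort(self, dev_cohort):
        cohort = dev_cohort.cohort
        for strategy, arm in ((Strategy.OBP_ABP, "office"), (Strategy.HBP_ABP, "home")):
            counts = evaluate_strategy(
                cohort, strategy, office_zones=OFFICE_ZONES, home_zones=HOME_ZONES
            )
            table = tabulate_zone_phenotypes(cohort, OFFICE_ZONES if arm == "office" else HOME_ZONES, arm)
            assert counts == evaluate_from_zone_table(table)

    def test_perfect_accuracy_when_screen_equals_reference(self):
        rng = np.random.default_rng(11)
        cohort = []
        for i in range(120):
            sbp = float(rng.uniform(105, 175))
            dbp = float(rng.uniform(65, 110))
            cohort.append(_subject(i, (sbp, dbp), (sbp, dbp), home=(sbp, dbp)))
        for strategy in Strategy:
            c = evaluate_strategy(cohort, strategy, office_zones=OFFICE_ZONES, home_zones=HOME_ZONES)
            assert c.fp == 0 and c.fn == 0
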