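"""End-to-end pipeline: generate/ingest -> aggregate -> zones -> evaluate -> report.

A run is described by a declarative :class:`RunConfig` (serializable to
JSON) naming the input source (simulate, a readings CSV, or a bundled /
external phenotype-by-zone count table), the zone mode (derive from the
cohort or fix externally), the strategies to evaluate, and the reference
standard.  The pipeline writes a :class:`ReportBundle`:

* ``zones.json`` — the zone boundaries used;
* ``table2.csv`` — phenotype-by-zone counts per arm;
* ``table3.csv`` — threshold-alone accuracy (all and excluding the
  intermediate zone);
* ``table4.csv`` — cascade accuracy per strategy;
* ``flow.csv`` — stage counts of each cascade (zone occupancy and
  ambulatory referrals);
* ``run.log`` — every validity exclusion with its reason.

Everything is deterministic given the seed in the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd

from .aggregation import (
    DEVELOPMENT_SCHEDULE,
    VALIDATION_SCHEDULE,
    AggregatedSubject,
    ScheduleSpec,
    aggregate_cohort,
)
from .cascade import (
    Strategy,
    ZonePhenotypeTable,
    diagnose,
    evaluate_from_zone_table,
    evaluate_strategy,
    evaluate_threshold_alone,
    tabulate_zone_phenotypes,
)
from .io import (
    format_metrics_frame,
    read_readings_csv,
    read_zone_table_csv,
    write_readings_csv,
    write_subjects_csv,
    write_zone_table_csv,
    write_zones_json,
)
from .metrics import DiagnosticMetrics, compute_metrics
from .reference_tables import fixed_boundaries, zone_table
from .synthetic import CohortParams, apply_screening, generate_cohort, latent_profiles_frame
from .zones import ZoneBoundaries, derive_zone_boundaries

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger(__name__)

Mode = Literal["simulate", "from-readings", "from-table"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: Mode
    outdir: str = "results/run"
    seed: int = 0
    cohort_params: Optional[CohortParams] = None  # simulate mode
    readings_path: Optional[str] = None  # from-readings mode
    table_population: Literal["development", "validation"] = "development"
    table_paths: Optional[dict] = None  # from-table: {"office": path, "home": path}
    zone_mode: Literal["derive", "fixed"] = "derive"
    fixed_office_zones: Optional[ZoneBoundaries] = None
    fixed_home_zones: Optional[ZoneBoundaries] = None
    strategies: Sequence[Strategy] = (Strategy.OBP_ABP, Strategy.OBP_HBP_ABP, Strategy.HBP_ABP)
    reference: Literal["daytime", "24h"] = "daytime"
    scheme: Literal["development", "validation"] = "development"
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "from-readings", "from-table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.cohort_params is None:
            raise ValueError("simulate mode requires cohort_params")
        if self.mode == "from-readings" and not self.readings_path:
            raise ValueError("from-readings mode requires readings_path")
        if self.zone_mode == "fixed":
            for b in (self.fixed_office_zones, self.fixed_home_zones):
                if b is None:
                    continue
        if not (0 < self.confidence_level < 1):
            raise ValueError("confidence level must be in (0, 1)")

    @property
    def schedule(self) -> ScheduleSpec:
        if self.mode == "simulate" and self.cohort_params is not None:
            return self.cohort_params.schedule
        return DEVELOPMENT_SCHEDULE if self.scheme == "development" else VALIDATION_SCHEDULE


@dataclass
class ReportBundle:
    """In-memory results of a run, plus the paths the tables were written to."""

    outdir: Path
    zones: dict[str, ZoneBoundaries]
    tables: dict[str, ZonePhenotypeTable]
    threshold_metrics: dict[str, DiagnosticMetrics]
    cascade_metrics: dict[str, DiagnosticMetrics]
    flow: pd.DataFrame
    n_analyzed: int


def _setup_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bptriage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def _analyzable(aggs: Sequence[AggregatedSubject], reference: str) -> list[AggregatedSubject]:
    kept = []
    for a in aggs:
        if not a.home_valid:
            log.info("exclusion subject=%s filter=home_validity", a.subject_id)
            continue
        ref = a.daytime_abp if reference == "daytime" else a.abp_24h
        if not a.abp_valid or ref is None:
            log.info("exclusion subject=%s filter=ambulatory_validity", a.subject_id)
            continue
        kept.append(a)
    return kept


def _subject_level_run(config: RunConfig, outdir: Path) -> ReportBundle:
    if config.mode == "simulate":
        subjects, profiles = generate_cohort(config.cohort_params)
        latent_profiles_frame(profiles).to_csv(outdir / "latent.csv", index=False, float_format="%.3f")
        screened = apply_screening(subjects, config.cohort_params.screening_threshold)
        log.info(
            "screening: %d of %d subjects retained (office >= %.0f/%.0f)",
            len(screened),
            len(subjects),
            config.cohort_params.screening_threshold.sbp,
            config.cohort_params.screening_threshold.dbp,
        )
        write_readings_csv(screened, outdir / "readings.csv")
    else:
        screened = read_readings_csv(config.readings_path)

    aggs = aggregate_cohort(screened, scheme=config.scheme, schedule=config.schedule)
    write_subjects_csv(aggs, outdir / "subjects.csv")
    cohort = _analyzable(aggs, config.reference)
    log.info("analysis cohort: %d of %d aggregated subjects valid", len(cohort), len(aggs))
    if not cohort:
        raise RuntimeError(
            f"no analyzable subjects remain ({len(aggs)} aggregated, all excluded "
            "by validity filters; see run.log)"
        )

    if config.zone_mode == "derive":
        zones = {
            "office": derive_zone_boundaries(cohort, "office", config.reference),
            "home": derive_zone_boundaries(cohort, "home", config.reference),
        }
    else:
        zones = {
            "office": config.fixed_office_zones or fixed_boundaries("office"),
            "home": config.fixed_home_zones or fixed_boundaries("home"),
        }

    tables = {
        arm: tabulate_zone_phenotypes(cohort, zones[arm], arm, config.reference)
        for arm in ("office", "home")
    }

    level = config.confidence_level
    threshold_metrics = {}
    for arm in ("office", "home"):
        threshold_metrics[f"{arm}_all"] = compute_metrics(
            evaluate_threshold_alone(tables[arm], exclude_intermediate=False), level
        )
        try:
            threshold_metrics[f"{arm}_excluding_intermediate"] = compute_metrics(
                evaluate_threshold_alone(tables[arm], exclude_intermediate=True), level
            )
        except ValueError as exc:
            # small cohorts can lose a whole reference class with the
            # intermediate zone excluded; report the other panels anyway
            log.info("threshold-alone panel %s excluding intermediate unavailable: %s", arm, exc)

    cascade_metrics = {}
    flow_rows = []
    for strategy in config.strategies:
        counts = evaluate_strategy(
            cohort, strategy, office_zones=zones["office"], home_zones=zones["home"],
            reference=config.reference,
        )
        cascade_metrics[strategy.value] = compute_metrics(counts, level)
        outcomes = [
            diagnose(s, strategy, zones["office"], zones["home"], config.reference)
            for s in cohort
        ]
        stage_counts = pd.Series([o.terminal_stage for o in outcomes]).value_counts()
        for stage in ("office", "home", "ambulatory"):
            flow_rows.append(
                {
                    "strategy": strategy.value,
                    "stage": stage,
                    "n_terminal": int(stage_counts.get(stage, 0)),
                }
            )
    flow = pd.DataFrame(flow_rows)
    return ReportBundle(
        outdir=outdir,
        zones=zones,
        tables=tables,
        threshold_metrics=threshold_metrics,
        cascade_metrics=cascade_metrics,
        flow=flow,
        n_analyzed=len(cohort),
    )


def _table_level_run(config: RunConfig, outdir: Path) -> ReportBundle:
    if config.table_paths:
        tables = {arm: read_zone_table_csv(path) for arm, path in config.table_paths.items()}
    else:
        tables = {
            arm: zone_table(config.table_population, arm) for arm in ("office", "home")
        }
    zones = {"office": fixed_boundaries("office"), "home": fixed_boundaries("home")}

    level = config.confidence_level
    threshold_metrics = {}
    for arm, table in tables.items():
        threshold_metrics[f"{arm}_all"] = compute_metrics(
            evaluate_threshold_alone(table, exclude_intermediate=False), level
        )
        threshold_metrics[f"{arm}_excluding_intermediate"] = compute_metrics(
            evaluate_threshold_alone(table, exclude_intermediate=True), level
        )

    # Count tables carry one arm each, so only the single-arm cascades are
    # recomputable; the office-home cascade needs the joint distribution.
    cascade_metrics = {}
    flow_rows = []
    strategy_arm = {Strategy.OBP_ABP: "office", Strategy.HBP_ABP: "home"}
    for strategy in config.strategies:
        arm = strategy_arm.get(strategy)
        if arm is None or arm not in tables:
            log.info(
                "strategy %s not recomputable from single-arm count tables; skipped",
                strategy.value,
            )
            continue
        table = tables[arm]
        cascade_metrics[strategy.value] = compute_metrics(evaluate_from_zone_table(table), level)
        zone_totals = table.counts.sum(axis=0)
        for zone_name, n in zone_totals.items():
            flow_rows.append(
                {
                    "strategy": strategy.value,
                    "stage": f"{arm}_{zone_name}_zone",
                    "n_terminal": int(n),
                }
            )
    flow = pd.DataFrame(flow_rows)
    n_total = max(t.n_total for t in tables.values())
    return ReportBundle(
        outdir=outdir,
        zones=zones,
        tables=tables,
        threshold_metrics=threshold_metrics,
        cascade_metrics=cascade_metrics,
        flow=flow,
        n_analyzed=n_total,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute a configured run and write the full report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        if config.mode == "from-table":
            bundle = _table_level_run(config, outdir)
        else:
            bundle = _subject_level_run(config, outdir)

        write_zones_json(list(bundle.zones.values()), outdir / "zones.json")
        for arm, table in bundle.tables.items():
            write_zone_table_csv(table, outdir / f"table2_{arm}.csv")
        format_metrics_frame(bundle.threshold_metrics).to_csv(outdir / "table3.csv")
        format_metrics_frame(bundle.cascade_metrics).to_csv(outdir / "table4.csv")
        bundle.flow.to_csv(outdir / "flow.csv", index=False)

        # cross-foot check: every table's cells sum to its stated total
        for arm, table in bundle.tables.items():
            assert table.counts.to_numpy().sum() == table.n_total
        log.info("report written to %s (n=%d)", outdir, bundle.n_analyzed)
        return bundle
    finally:
        logging.getLogger("bptriage").removeHandler(handler)
        handler.close()
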