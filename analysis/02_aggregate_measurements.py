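#!/usr/bin/env python
"""Aggregate reading-level data to per-subject BP values.

Applies the protocol rules: index-arm office mean over three visits,
home mean after the first-evening/second-morning discard with the
5-day duplicate-measurement validity rule, and the daytime-window
ambulatory mean with the >70% / >=14 daytime / >=7 nighttime validity
rule.  Reports the attrition the validity filters cause, as a cohort
flow (recruited -> analyzable).
"""

from pathlib import Path

from bptriage.aggregation import aggregate_cohort
from bptriage.io import read_readings_csv, write_subjects_csv

IN = Path("results/cohort/readings.csv")
OUT = Path("results/cohort/subjects.csv")


def main() -> None:
    subjects = read_readings_csv(IN)
    aggs = aggregate_cohort(subjects, scheme="development")
    write_subjects_csv(aggs, OUT)
    n = len(aggs)
    n_home = sum(a.home_valid for a in aggs)
    n_abp = sum(a.abp_valid for a in aggs)
    n_both = sum(a.home_valid and a.abp_valid for a in aggs)
    print(f"aggregated {n} screened subjects")
    print(f"  valid home BP:        {n_home} ({100 * n_home / n:.1f}%)")
    print(f"  valid ambulatory BP:  {n_abp} ({100 * n_abp / n:.1f}%)")
    print(f"  analyzable (both):    {n_both} ({100 * n_both / n:.1f}%)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
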