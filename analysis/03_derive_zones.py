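#!/usr/bin/env python
"""Derive the intermediate-zone boundaries by ROC calibration.

The lower boundary of each modality is the largest observed cut-off
keeping sensitivity >= 95% for daytime ambulatory hypertension
(>= 135/85 mmHg); the upper boundary the smallest cut-off reaching 95%
specificity; both rounded to the nearest multiple of 5 mmHg.  Prints
the raw and rounded cut-offs next to the published zones
(office 130-145/80-95, home 120-145/80-95 mmHg).
"""

from pathlib import Path

from bptriage.aggregation import aggregate_cohort
from bptriage.io import read_readings_csv, write_zones_json
from bptriage.zones import derive_raw_cutoffs, derive_zone_boundaries

IN = Path("results/cohort/readings.csv")
OUT = Path("results/cohort/zones.json")
PUBLISHED = {"office": (130, 80, 145, 95), "home": (120, 80, 145, 95)}


def main() -> None:
    subjects = read_readings_csv(IN)
    cohort = [a for a in aggregate_cohort(subjects) if a.home_valid and a.abp_valid]
    print(f"derivation cohort: {len(cohort)} subjects")
    zones = []
    for modality in ("office", "home"):
        raw = derive_raw_cutoffs(cohort, modality)
        z = derive_zone_boundaries(cohort, modality)
        zones.append(z)
        pub = PUBLISHED[modality]
        print(f"{modality}:")
        print(f"  raw cut-offs  {raw.lower_sbp:.1f}/{raw.lower_dbp:.1f} (95% sens), "
              f"{raw.upper_sbp:.1f}/{raw.upper_dbp:.1f} (95% spec)")
        print(f"  rounded zones normotension < {z.lower.sbp:.0f}/{z.lower.dbp:.0f}, "
              f"hypertension >= {z.upper.sbp:.0f}/{z.upper.dbp:.0f} "
              f"(published {pub[0]}/{pub[1]} - {pub[2]}/{pub[3]})")
    write_zones_json(zones, OUT)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
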