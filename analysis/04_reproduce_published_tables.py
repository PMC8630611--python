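#!/usr/bin/env python
"""Recompute the published accuracy panels from the bundled count tables.

The published phenotype-by-zone counts determine every accuracy metric
of the single-arm strategies exactly: cascade errors are the white-coat
hypertensives in the hypertension zone plus the masked hypertensives in
the normotension zone.  Runs the count-level pipeline on the
development (n=256) and validation (n=399) tables and writes the
threshold-alone and cascade metric panels.
"""

from bptriage.pipeline import RunConfig, run_pipeline


def main() -> None:
    for population in ("development", "validation"):
        bundle = run_pipeline(
            RunConfig(
                mode="from-table",
                table_population=population,
                outdir=f"results/published_{population}",
            )
        )
        print(f"{population} population (n={bundle.n_analyzed}):")
        for name, m in bundle.cascade_metrics.items():
            print(
                f"  {name:8s} sens {m.sensitivity.percent[0]:5.1f}%  "
                f"spec {m.specificity.percent[0]:5.1f}%  "
                f"acc {m.accuracy.percent[0]:5.1f}%  AUC {m.auc.estimate:.3f}"
            )
        office = bundle.threshold_metrics["office_all"]
        print(
            f"  office threshold alone: sens {office.sensitivity.percent[0]:.1f}% "
            f"acc {office.accuracy.percent[0]:.1f}%"
        )
        print(f"  report in {bundle.outdir}")


if __name__ == "__main__":
    main()
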