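# bptriage

Triage algorithm for diagnosing hypertension with office, home, and
ambulatory blood pressure.

## The problem

Office BP alone misdiagnoses two large groups of patients referred for
suspected hypertension: **white-coat hypertension** (high office BP,
normal daytime ambulatory BP) and **masked hypertension** (normal office
BP, high daytime ambulatory BP). Ambulatory BP monitoring (ABPM)
resolves both but is too costly and burdensome to apply to everyone.

The triage algorithm implemented here splits office and home BP into
three zones:

* **normotension zone** — below both lower cut-offs: hypertension ruled
  out, no ABPM needed;
* **hypertension zone** — at or above either upper cut-off:
  hypertension ruled in, no ABPM needed;
* **intermediate zone** — in between: daytime ambulatory BP
  (hypertensive at ≥ 135/85 mmHg, the reference standard) decides.

The cut-offs are calibrated on a development cohort by ROC analysis:
the lower boundary is the largest observed cut-off keeping **95 %
sensitivity** for daytime ambulatory hypertension, the upper boundary
the smallest reaching **95 % specificity**, each rounded to the nearest
multiple of 5 mmHg. On the development cohort this yields office zones
130–145/80–95 mmHg and home zones 120–145/80–95 mmHg, and three cascade
strategies:

* **OBP-ABP** — office zones decide; office-intermediate subjects get ABPM;
* **OBP-HBP-ABP** — office-intermediate subjects fall through to home
  zones; only home-intermediate subjects get ABPM;
* **HBP-ABP** — home zones decide; home-intermediate subjects get ABPM.

Because intermediate-zone subjects are classified by the reference
standard itself, a cascade errs exactly on the white-coat hypertensives
in the hypertension zone (false positives) and the masked hypertensives
in the normotension zone (false negatives). The published
phenotype-by-zone count tables of the development (n = 256) and
validation (n = 399) cohorts therefore determine the single-arm
accuracy panels exactly, and this package bundles those counts as its
count-level input. Since the underlying reading-level data were never
deposited, a calibrated synthetic cohort generator (multivariate-normal
latent BP with measurement noise and enrolment screening at office
≥ 140/90 mmHg) stands in for them end to end.

The package is intended for methodologists studying sequential
diagnostic testing and for reproducing/perturbing this triage design:
every stage — cohort simulation, measurement aggregation, ROC zone
derivation, cascade evaluation, exact binomial confidence intervals —
is an importable, tested function.

## Worked example

Recompute the development-population accuracy panel from the published
counts (TP = 186, FP = 7, FN = 2, TN = 61 for the office cascade):

```python
from bptriage import compute_metrics, evaluate_from_zone_table
from bptriage.reference_tables import zone_table

counts = evaluate_from_zone_table(zone_table("development", "office"))
m = compute_metrics(counts)
print(counts)
print(f"sensitivity {m.sensitivity.percent[0]:.1f}% "
      f"({m.sensitivity.percent[1]:.1f}-{m.sensitivity.percent[2]:.1f})")
print(f"specificity {m.specificity.percent[0]:.1f}%  "
      f"accuracy {m.accuracy.percent[0]:.1f}%  AUC {m.auc.estimate:.3f}")
```

prints

```
ConfusionCounts(tp=186, fp=7, fn=2, tn=61)
sensitivity 98.9% (96.2-99.9)
specificity 89.7%  accuracy 96.5%  AUC 0.943
```

i.e. the office cascade misses 2 of 188 ambulatory hypertensives and
falsely rules in 7 of 68 normotensives, with the exact Clopper–Pearson
interval shown for sensitivity.

The same is available from the shell:

```bash
bptriage reproduce                       # development population panels
bptriage simulate -n 2000 --seed 1       # synthetic screened cohort
bptriage evaluate --mode simulate -n 2000 --seed 1   # full pipeline
```

The numbered scripts under `analysis/` run the whole study as a
narrative: `01_simulate_cohort.py` → `02_aggregate_measurements.py` →
`03_derive_zones.py` → `04_reproduce_published_tables.py` →
`05_evaluate_strategies.py`, writing their tables under `results/`.

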