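# Methods

## Measurement model and aggregation rules

Each subject is summarized by three BP pairs (mmHg):

* **office** — three visits, triplicate readings. Development scheme:
  the *index arm* is the arm with the higher visit-1 mean (SBP decides,
  ties fall to DBP, then to the right arm) and office BP is the mean of
  all index-arm readings across visits. Validation scheme: per-arm
  means over all visits are formed first and the higher-mean arm's mean
  is used. Readings and visits are weighted equally (the protocol does
  not state a visit weighting).
* **home** — seven days, morning and evening triplicate sessions. The
  day-1 evening and day-2 morning sessions are discarded; each
  remaining session contributes the mean of its first two readings
  (a lone reading stands for itself, third readings are ignored); home
  BP is the unweighted mean over session values. Sessions, not days,
  are weighted equally — the session is the protocol's averaging unit
  and this keeps the noise-free limit exact. Validity requires, *after*
  the discard, at least 5 distinct days with a ≥ 2-reading morning
  session and at least 5 with a ≥ 2-reading evening session; the
  discard-first order is chosen because the discarded sessions are
  never analysed. A day-8/9 morning session (allowed in the validation
  protocol) is accepted like any other.
* **ambulatory** — half-hourly automated readings over 25 h. A
  recording is valid only if strictly more than 70 % of attempts
  succeeded, with ≥ 14 valid readings in the daytime window and ≥ 7 in
  the nighttime window (00:00–06:00). Daytime windows are 10:00–20:00
  (development) or 09:00–21:00 (validation); all clock windows are
  half-open `[start, end)` on plain clock time, with no time-zone
  logic. The daytime-window mean is the reference standard; the mean
  over all valid readings is the 24-h alternative.

Diagnostic thresholds: office ≥ 140/90 mmHg; home and daytime
ambulatory ≥ 135/85 mmHg; each an or-rule over SBP/DBP. Phenotypes are
the 2×2 concordance of screening test vs reference: NT, WH (white-coat),
MH (masked), SH (sustained).

## Zone derivation

Against the binary reference truth (daytime ambulatory ≥ 135/85), SBP
and DBP cut-offs are derived independently, candidates being the
observed values themselves (the development study's non-integer raw
cut-offs, e.g. 130.2 mmHg, indicate observed-value thresholds rather
than interpolation):

* lower boundary — the **largest** candidate whose sensitivity
  (fraction of reference positives at or above it) is ≥ 0.95;
* upper boundary — the **smallest** candidate whose specificity
  (fraction of reference negatives strictly below it) is ≥ 0.95.

Both are rounded to the nearest multiple of 5 mmHg, exact midpoints
rounding up (a fixed documented rule; the published values never sit on
a midpoint). Zone assignment uses worst-component logic: either
component at/above its upper cut-off rules in; both components below
their lower cut-offs rule out; everything else is intermediate. If
rounding collapses a zone (lower ≥ upper — e.g. for a near-perfect
screening test, whose 95 %-sensitivity cut-off lies *above* its
95 %-specificity cut-off) the derivation fails loudly and reports the
raw cut-offs; a perfect test needs no confirmatory zone.

The 24-h reference mode reuses the same machinery and keeps the 135/85
threshold unless configured otherwise; no separate 24-h threshold is
assumed.

## Cascade evaluation

Strategies terminate in the normotension/hypertension zones and refer
intermediate-zone subjects onward (to home BP and/or ambulatory BP).
Subjects resolved by the reference standard are scored as correct by
construction — mirroring the arithmetic that makes the published count
tables sufficient statistics for the single-arm panels. The identity

```
errors = WH in hypertension zone + MH in normotension zone
```

(plus the structurally empty NT-in-hypertension and SH-in-normotension
cells) holds on every input and is asserted property-style in the
tests. The subject-level and count-level evaluation routes are
cross-checked against each other at run time for the single-arm
strategies. The office→home→ambulatory cascade requires the joint
office×home distribution and is therefore only computable on
subject-level data, not from the published single-arm tables.

The home-arm phenotype totals of a published table differ slightly from
the office-arm totals of the same cohort (development NT 47 vs 48, WH
21 vs 20; validation reference-positives 326 vs 325) because home
phenotypes use the home threshold; tables are evaluated exactly as
printed.

## Confidence intervals

All proportion metrics carry exact central Clopper–Pearson intervals
(beta-quantile closed form). The method is an assumption — the source
analyses name only their software — but it reproduces every
spot-checked printed interval (e.g. 186/188 → 96.2–99.9 %). The AUC of
a single operating point is (sensitivity + specificity)/2; its interval
uses the Hanley–McNeil standard error, is labelled `hanley-mcneil`,
and is not expected to match published AUC intervals (whose method is
not identifiable). Two estimates are called statistically different
only when their closed confidence intervals do not overlap. Percentages
are reported to one decimal, proportions to three.

## Synthetic cohort generator

The study cohorts were never deposited, so the generator emulates the
screened population the analysis assumes:

* a latent 6-vector per subject — office, home, daytime-ambulatory
  SBP/DBP means — from a multivariate normal;
* readings = latent value + independent noise (SD 6 mmHg office and
  home, 12 mmHg ambulatory), plus one **between-visit office effect**
  (SD 7 mmHg, shared by all readings of a visit, both arms and both
  components). The visit effect is day-to-day BP variability; it is
  what lets an enrolment screen on the first-visit mean (office
  ≥ 140/90) produce the regression to the mean seen in real screened
  cohorts, where roughly a third of enrolled patients are
  office-normotensive on the full three-visit average. Noise-free
  analyses set it to 0 together with the reading noise;
* home sessions are dropped, and ambulatory attempts fail,
  independently with probability 0.05;
* ambulatory readings in the nighttime window sit 10 mmHg below the
  daytime latent value (nocturnal dip); the daytime offset is 0 so the
  daytime-window mean estimates the latent value exactly in the
  noise-free limit;
* both arms are simulated as the same latent value plus independent
  noise plus a configurable inter-arm offset (default 0);
* extreme noise draws are clamped to the physiological schema
  (40–300 / 20–200 mmHg, systolic above diastolic);
* one root seed with an independent substream per subject, so growing
  the cohort never perturbs earlier subjects.

### Calibration

The defaults are **pre-screening** population constants, calibrated
once so that the **screened** cohort approximates the development
population: latent mean (132.0, 84.4, 128.7, 83.2, 128.5, 83.6), SD
(12.0, 9.3, 13.0, 9.7, 14.0, 12.2), SBP–DBP correlations 0.90 / 0.80 /
0.86 within office / home / ambulatory, and between-modality
correlations 0.62 (office–home), 0.80 (office–daytime), 0.72
(home–daytime), with cross terms by a product rule. The discordant
phenotypes arise purely from the office–daytime correlation being
below 1, not from explicit labels. At the standard run size (2000
pre-screening subjects, ~730 screened) the screened cohort's true
phenotype mix lands within ~2 percentage points of the development
population (NT 18.8 / WH 7.8 / MH 16.4 / SH 57.0 %), the ROC-derived
office boundaries within 5 mmHg of the published 130–145/80–95, the
office intermediate-zone share within 2 points of the published 48.8 %,
and over 80 % of WH + MH mass in the intermediate zone.

Two deliberate departures from a literal reading of the published
cohort tables:

* exact post-screening *moment* matching is not attempted (prevalences
  are the contract); screening selection makes the screened latent
  distribution non-normal, and the screened SDs run a little below the
  published ones;
* the *measured* office-hypertension share post-screening (~75 %)
  exceeds the published 64.8 %, because here the screening occasion is
  visit 1 of the office average itself, whereas the study screened at a
  separate earlier clinic visit. The true-phenotype mix, the zone flow,
  and the derived boundaries — the quantities the analysis consumes —
  are unaffected.

The validation preset shifts the latent means by the published
between-cohort differences (e.g. +2.2 mmHg home SBP) and switches the
daytime window; no mechanism for the cohort difference is modelled.

What the generator does **not** emulate: autocorrelated ambulatory
noise, seasonal/treatment effects, device error structure, informative
missingness. Passing tests therefore demonstrate correctness of the
algorithmic pipeline under the stated sampling model, not robustness to
those real-data features.

## Problem sizes and numerical choices

The standard synthetic run uses 2000 pre-screening subjects (~730
screened, ~690 analyzable) — the scale at which the published flow
percentages are stable while the whole pipeline stays interactive; the
Monte-Carlo prevalence oracle uses 10^6 latent draws. ROC cut-off
searches are exact over observed candidates (no interpolation);
tie-breaks are as stated above; means are plain unweighted averages, so
aggregation is permutation-invariant up to floating-point summation
order. Degenerate inputs (empty windows, missing arms, single-class
truth, collapsed zones, empty post-filter cohorts) raise explicit
errors naming the offending subject or quantity rather than returning
defaults.
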