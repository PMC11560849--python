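# Methods

## Scope and model

The package evaluates an alerting classifier whose internal score is opaque:
only its fired-alert events (timestamp, integer score, chart-viewed flag)
are consumed. The quantity under study is the diagnostic accuracy of those
alerts against an electronically phenotyped sepsis label, plus how a
rate-matched random alarm would have scored, and how far ahead of onset the
alerts actually arrived. The predictive model itself is deliberately out of
scope: nothing here estimates or refits it.

## SOFA scoring

The six consensus organ sub-scores are tabulated in
`sofa_engine` (respiration, coagulation, liver, cardiovascular, CNS, renal;
each 0–4, total 0–24). Conventions that the consensus table leaves implicit
and we fix explicitly:

- **Bin boundaries** are left-closed on the less-severe side: platelets
  exactly 100 → 1, 99.9 → 2; bilirubin exactly 1.2 → 1; creatinine exactly
  1.2 → 1. GCS uses the printed integer bands; MAP exactly 70 → 0.
- **Respiratory support**: PF < 200 without ventilation caps at 2; scores 3
  and 4 require the ventilated flag.
- **Cardiovascular** is the maximum over the hypotension and per-drug dose
  rules; any positive dose engages its rule.
- **Renal** is the worse of the creatinine and 24-h urine pathways.

Grid: 15-minute step anchored at ED arrival (`step_minutes` must divide 60),
half-open bins, `floor(stay/step)+1` points, so a same-instant
admission-discharge pair still yields a one-point series.

Missing data: last observation carried forward within a 24-hour lookback
(configurable). An organ with no observation in the lookback scores 0 —
assumed normal — and is flagged in a per-organ imputation mask. Scoring
unmeasured organs as failing would label nearly every ED patient septic;
the mask exists so users can quantify how much of a score is imputed. The
lookback and default are configuration, not claims about any particular
production query.

## Sepsis-3 phenotype

Sepsis = first grid time with total SOFA ≥ baseline + 2, **and** ≥1 blood
culture **and** ≥1 antibiotic ordered at any time in the encounter. Two
baseline modes are implemented because "changed by 2 or more points" admits
both readings: `first_score` (default; within-encounter reference at the
first grid point) and `zero` (consensus assumption of no prior dysfunction;
an encounter already at ≥2 at its first grid point has onset there). The
order requirement is encounter-level, with no temporal bracketing around
onset — the stricter suspected-infection windows of other phenotypes are
intentionally not applied. Adding an order can only move a label from
non-sepsis to sepsis (tested property).

## Windowed evaluation

The windowed matrix judges each alert at a 6-hour forward horizon, closed at
both ends (`onset == alert + 6 h` is a hit). A septic encounter alerted
outside its window is a **false positive**, not an excluded case: the
alerted/not-alerted margins stay fixed, and the "positive" margin is
(onset-within-window) + (septic, never alerted). This reclassification rule
is the only reading that reproduces the published margin arithmetic
(`reconstruct_windowed_margins` demonstrates it from the four published
totals through the production code path). The first fired alert per
encounter anchors the window; windowed and encounter-level matrices share
FN and TN by construction and the pipeline asserts it on every run.
Zero-denominator metrics are reported as undefined, never 0. Wilson score
intervals are used for the optional 95% CIs (statsmodels).

## Random-alert null

Default mechanism: per encounter, one pseudo-alert with probability equal to
the observed alert prevalence, at a time uniform over the stay; a
per-15-minute-interval geometric variant is available. The published
description of the comparison alarm does not pin down the mechanism, so the
minimal marginal-rate-matched null is the default and its printed baseline
numbers are treated as indicative, not as targets. Analytic anchor used in
testing: in encounter mode E[specificity] = 1 − p. The adjustment is a
subtraction floored at zero — forced by the published arithmetic
(14.7% − 1.27% = 13.43%) rather than a ratio-style correction.

## Lead times

Lead = onset − first fired alert, minutes, positive when the alert precedes
onset. The "80% interval" is the empirical 10th–90th percentile interval
(numpy linear interpolation): a confidence interval for a median of ~0 with
n in the thousands could not span −6 to +12 hours, so the printed spread is
read as distributional. Ties (lead 0) count with "alert at/before onset";
the before/at/after counts are also reported separately so any tie rule can
be reconstructed.

## Characteristics table

Row percentages (share of each category's row that is/isn't septic),
Pearson χ² of independence without continuity correction for tables larger
than 2×2; Yates correction config-exposed for 2×2; likelihood-ratio variant
available for multi-level variables. Variables with a zero expected cell are
reported untested with a warning. Age is banded 18–44 / 45–64 / 65+.
Known open issue: a plain χ² on the published 5×2 race strata is strongly
significant, while the source table prints a non-significant p obtained
from an unpublished binomial regression; the package reports what the χ²
(or G-test) actually computes and does not attempt to reproduce that value.

## Synthetic cohort

`synthetic_cohort` emulates the study conditions rather than physiology:

- **Marginals**: 3.7% sepsis prevalence, 4.9% fired-alert prevalence,
  P(alert | sepsis) = 2253/5433; the non-sepsis alert rate is solved from
  the margins, with joint infeasibility rejected at configuration time.
- **Lead times**: two-sided mixture — 550/2253 within the 6-h window
  (uniform 5–355 min), 1126/2253 after onset (uniform −402…−5 min),
  remainder too early (uniform 365–720 min). Component supports are placed
  strictly inside/outside the closed window so planted confusion counts are
  exact, and the endpoints echo the reported 80% lead-time spread.
- **Trajectories**: piecewise-constant step profiles. Everyone gets normal
  baseline vitals/labs at arrival (all sub-scores 0); septic encounters get
  a platelet drop crossing two severity bins exactly at the planted onset
  grid time, so the phenotype's first crossing is the planted onset by
  construction. Non-septic encounters are flat or carry a single 1-point
  MAP wobble; 10% of them also get noise blood-culture + antibiotic orders,
  and 15% of all encounters get decoy alert events (sub-threshold or
  unviewed) — all structures that must *not* produce labels or fired
  alerts.
- **Stays**: lognormal (median 8 h, σ = 0.75 log-minutes, floor 2 h),
  extended where needed to contain planted events; onsets land on the grid
  12–36 h after arrival so even the widest planted lead keeps the alert
  inside the stay. These are modeling choices — no length-of-stay
  distribution was published.
- **Demographics** are sampled independently of the sepsis label from the
  published marginal proportions of a predominantly Hispanic/Black county
  ED population; the generator does not plant demographic–sepsis
  associations.

What passing the round-trip tests shows: the pipeline is internally
consistent — planted structure in, identical counts out — under clean step
trajectories, exact grid alignment and complete order data. What it does not
show: robustness to the messiness of real extracts (irregular sampling,
unit errors, boundary-straddling trajectories, order-before-arrival
artifacts), beyond what the row-level validation layer rejects explicitly.

## Problem sizes and determinism

The scaled end-to-end reproduction uses 14 600 encounters (one tenth of the
published cohort), where the four windowed metrics are expected to fall
within 3 binomial standard errors of the published values; the null model
uses ≥500 replicates with a 3-Monte-Carlo-SE criterion. All randomness flows
from `numpy.random.default_rng` seeds; identical seed + config produce
byte-identical cohort files, and stage seeds are derived as seed, seed+1,
seed+2.

## Limitations

- The SOFA threshold table is the adult consensus table; no pediatric
  variant, and no qSOFA or alternative severity scores.
- The phenotype's baseline ambiguity (first-score vs zero) is exposed, not
  resolved; results can differ between modes for encounters arriving with
  existing organ dysfunction.
- The null model's mechanism is underdetermined by its published
  description; two plausible mechanisms are offered.
- The generator's step profiles make onset recovery exact by design; they
  are a verification instrument, not a simulator of clinical time series.
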