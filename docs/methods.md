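# Methods

This note records the scientific and numerical choices behind the package:
the scoring rubric's boundary conventions, the calibration of the synthetic
cohort generator, the exact definitions of the statistics, and what the
synthetic data can and cannot show about real admission cohorts.

## The rubric

The MSNS grades eight admission parameters 0/1/2 and sums them (0–16,
lower = sicker).  The published band table leaves boundary membership and
two clinical presentations ambiguous; the package fixes one consistent
reading, chosen so the three bands of every parameter partition the
admissible input space, with every interval closed on the side adjacent to
the score-2 (normal) band:

| parameter | score 0 | score 1 | score 2 |
|---|---|---|---|
| respiratory effort | apnea/grunt, or RR < 40 | RR > 60 (± retractions) | RR ∈ [40, 60] |
| heart rate (/min) | < 100 (incl. asystole) | > 160 | [100, 160] |
| axillary temperature (°C) | < 36 | [36, 36.5) or > 37.5 | [36.5, 37.5] |
| capillary refill (s) | > 5 | [3, 5] | < 3 |
| random blood sugar (mg/dl) | < 40 | [40, 60] | > 60 |
| SpO₂ room air (%) | < 85 | [85, 92] | > 92 |
| gestational age (wk) | < 32 | [32, 37) | ≥ 37 |
| birth weight (kg) | < 1.5 | [1.5, 2.5) | ≥ 2.5 |

Two presentations have no published band and are decided here, flagged as
package choices rather than inferred intent:

* **Bradypnea** (RR < 40 without apnea or grunting) scores **0** —
  clinically at least as ominous as apnea.
* **Fever** (> 37.5 °C) scores **1** — abnormal, but distinct from the
  hypothermia score-0 band.

Retractions are recorded but never score-determining (tachypnea scores 1
"with or without retractions").  Gestational age accepts obstetric
`weeks+days` notation (`"36+6"` → 36 + 6/7), so the upper edge of the
middle band is strictly below 37.0 completed weeks; "2.49" in the published
birth-weight band is read as the open upper edge of [1.5, 2.5).  Scoring
never imputes: a record missing a field its score needs is rejected at
validation with its id and field named, matching a score designed to be
computed once from observed admission vitals.  The band constants ship as
data (`data/rubric.csv`), not code.

## Synthetic cohorts

No record-level data accompany the study this package targets, so a seeded
generator stands in for the cohort at two levels.

**Score level.**  Totals are integers 0–16, drawn per outcome group as
`round(clip(Normal(μ*, σ), 0, 16))`.  Clipping and rounding shift the mean
of the latent normal (at the discharged calibration the naive construction
loses ≈ 0.08 points to the upper clip), so the latent location μ* is not
the target mean itself: it solves, by Brent's method on a closed-form sum of
normal CDFs, the equation *mean of the discretized distribution = target*.
The discretized mean is continuous and strictly increasing in μ, so the
solution is unique and the emitted scores hit the configured group means
exactly in expectation.  At σ = 0 the distribution is degenerate at
`round(target)`.

Defaults encode the study conditions: group means 9.11 (expired) and 12.9
(discharged), mortality 9/71, cohort size 71.  The group spreads are *not*
published; the defaults σ_expired = 2.4 and σ_discharged = 2.2 are
calibration constants of this package, chosen once so the binormal
separation Φ((12.9 − 9.11)/√(2.4² + 2.2²)) ≈ 0.878 matches the reported
discrimination (AUC ≈ 0.88).  Outcome counts are exact —
`round(n × mortality_fraction)` expired — never Bernoulli, and rows are
shuffled so order carries no outcome signal.  With only two group means and
an AUC the underlying score distributions are under-determined; the
generator therefore does not attempt to reproduce the reported cutoff ≤ 9 /
sensitivity 69% jointly, and a published report's exact 2×2 at its cutoff
should not be expected from it.

**Observation level.**  Each drawn total is realised as a full
physiological record by inverting the rubric: a composition of the total
into eight subscores ≤ 2 is chosen uniformly by direct enumeration (3⁸
candidates, cached per total), then each subscore is realised by a uniform
draw inside its band.  Open-ended bands use finite clinical caps (RR ≤ 90,
HR ∈ (160, 220], CRT ≤ 10 s, RBS ≤ 200 mg/dl, T ≥ 33 °C, GA ≥ 24 wk,
BW ≥ 0.5 kg, SpO₂ ≥ 50%); values are drawn from the band interior shrunk by
one rounding quantum per side, so the recorded (rounded) value provably
stays in-band and `compute_msns` returns the target exactly — a property
the suite checks for every target across 100 seeds.  A score-0 respiratory
effort is realised as apnea/grunt with the rate absent.  Each record uses a
random sub-stream keyed by `(seed, record index)`, so a record's
realisation is invariant to cohort size (the totals themselves necessarily
depend on n through the exact-count rule).  Demographics are seeded draws
at the reference cohort's proportions.

**The 71-record fixture** reproduces the published baseline marginals
*exactly* for every seed — 59/12 male/female, 14/57 preterm/term (preterm
< 37.0 weeks), 55/16 vaginal/caesarean, 58/13 primi/multi, 62/9
discharged/expired — with the joint assignment seeded-random, since no
cross-tabulations are published.  The rubric couples gestational age to the
total (a total of 16 forces term, a total ≤ 1 forces preterm), so preterm
status is assigned within those feasibility constraints and the
gestational-age subscore is pinned accordingly when inverting the rubric.

**What the synthetic data do not show.**  Real admission vitals are
correlated (a shocked neonate is cold, tachycardic and hypoglycaemic
together); the generator induces only the weak correlation that sharing a
target total implies.  Real cohorts carry missingness, transcription noise
and outcome states beyond discharged/expired; the generator emits none of
these.  Passing tests therefore validate the *machinery* — scoring,
statistics, calibration recovery — not the clinical performance of the
score on any real population.

## Statistics

All test statistics are computed from their definitions in
`msns.diagnostics`; scipy supplies only the reference distributions (normal
and χ² CDFs/quantiles).  Independent routes — an O(n²) pair-counting AUC, a
permutation enumeration oracle, `scipy.stats` and scikit-learn — appear in
the test suite as cross-checks, never as the implementation.

* **Percentages.**  Integer percentages truncate toward zero
  (`floor(100·k/n)`) by default: it is the only convention under which the
  reference baseline table is internally consistent (9/71 = 12.68 → "12%").
  Rounding is available as an option.
* **Mann–Whitney.**  U counts pairs with the first group's value lower
  (ties ½), computed via midranks.  The z statistic uses the tie-corrected
  variance n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))]; the two-sided p applies a
  continuity correction of ½ to |U − n₁n₂/2| (the reported z itself is
  uncorrected, as conventionally printed).  The correction matters: without
  it the normal p can miss the exact enumeration p by > 0.2 at small n,
  with it the gap stays below 0.1 for every tie-free configuration with
  both groups ≤ 8 — verified exhaustively in the suite.  When both groups
  have ≤ 8 observations the package switches automatically to the exact
  two-sided permutation p (full enumeration of labelings; the permutation
  distribution of U is symmetric about n₁n₂/2 even under ties, so
  two-sidedness by extremity equals the doubled tail).  Degenerate
  all-tied input yields z = 0, p = 1.
* **Chi-square.**  Pearson Σ(O−E)²/E with expected counts from the margins,
  after dropping all-zero rows/columns; df = (r−1)(c−1).  Expected cells
  < 5 set a warning flag but do not block the statistic — the 3×2
  band-by-outcome tables of a 71-neonate cohort with 9 deaths essentially
  always have small expected cells, and refusing to compute would make the
  per-parameter association table impossible.  No Yates correction.
* **ROC.**  Cutpoints are the 18 midpoints −0.5 … 16.5 of the integer
  grid; AUC is the trapezoid over (1 − specificity, sensitivity), which on
  this grid equals the tie-half concordance estimator to machine precision.
  The optimal cutoff maximises Youden's J over the grid, ties broken toward
  higher sensitivity, then the lower cutoff (so a run of equally perfect
  cutoffs reports its smallest member).  Cutoff semantics are always
  "positive if score ≤ c"; c = −1 (nothing positive) is a legal degenerate
  answer.
* **Intervals.**  Sensitivity, specificity, PPV and NPV carry Wilson score
  95% intervals — an addition to what score-validation reports typically
  print, chosen because Wald intervals are misleading at event counts as
  small as 9.  Computed bounds are clamped to [0, 1] and to contain the
  point estimate, absorbing floating-point noise at k = 0 or k = n.
  Predictive values are NaN when no record is predicted in the class.
* **Sample size.**  N = ⌈Z² p(1−p)/d²⌉ with Z the two-sided standard-normal
  quantile of the stated confidence (1.96 at 95%).  Note the study's own
  printed inputs (precision 1%, 98% confidence) do not yield its printed
  N = 71 under this formula; the operation implements the formula as
  defined and takes no position on that arithmetic.

## Pipeline and determinism

`run_analysis` executes acquire → validate → score → describe → associate →
compare → ROC in order; a failure aborts at its stage before any later
statistic is computed, and attrition (rows read/accepted/scored) is logged.
Reports carry the config echo, seed and package version, and contain no
timestamp, so identical configs produce byte-identical JSON.  With a
score-level synthetic input the physiology stages are skipped and the
report covers the total score only.

## Problem sizes

Calibration checks use 71,000 records for group means (sampling s.e.
≈ 0.025 on the expired mean with 9,000 expired) and 200,000 for the AUC
(s.e. well under 0.005); both complete in seconds.  Oracle-equivalence
suites run on ~100 random cohorts of up to ~200 records, and the exact
Mann–Whitney comparison is enumerated exhaustively for all group-size pairs
up to 8×8.
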