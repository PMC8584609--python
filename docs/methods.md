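# Methods

This note documents the models, defaults and numerical choices behind
`crpkin`, and what the synthetic data can and cannot show.

## Setting

After primary hip arthroplasty, serum CRP (mg/L) is drawn on clinical
routine roughly every 2–3 days until discharge. Day 0 is the operation
day; negative days are preoperative. The analysis concerns the
*immediate* postoperative course only — the package never extrapolates
beyond a patient's last inpatient draw, and missing values are simply
absent rows (no imputation).

Day 0 is excluded from the postoperative window
(`postoperative_subseries` keeps day ≥ 1): a day-0 draw may precede or
follow the operation and would mix pre- and post-surgical physiology.

## Peaks

A *local peak* is a sample strictly greater than both neighbors — a rise
in CRP preceded and followed by lower values. The *primary peak* is the
first day attaining the postoperative maximum (ties → earliest day);
boundary samples can be the primary peak but are never counted as
additional local peaks, since an unobserved neighbor cannot confirm a
rise. The *second peak* is the highest-valued local peak other than the
primary — second in magnitude, not in time, so it may precede the
primary maximum (this actually occurs in the worked eight-patient
cohort: a secondary peak at day 11 before a primary maximum at day 14).

`min_rise` (default 0 mg/L) optionally requires the rise to exceed a
noise floor on both sides; with real laboratory noise every blip is
otherwise a "peak".

## One-phase decay

Series are peak-normalized: x = days after the primary peak, y = CRP /
peak CRP, so every patient contributes (0, 1). Pooled points are fitted
with

    y = span · e^(−k·x) + plateau

by Levenberg–Marquardt least squares (scipy), initialized at
(span, k, plateau) = (0.7, 0.3, 0.25), relative parameter tolerance
1e−10, at most 500 iterations. The initialization sits in the
physiological ballpark (value ≈ 1 at the peak, residual CRP ≈ 25% of
peak) and the problem is benign enough that the optimum is insensitive
to it; determinism matters more than cleverness here. A fitted k ≤ 0 or
constant input raises a "no decay" error rather than returning a
meaningless curve. R² = 1 − SS_res/SS_tot on the fitted points.

The package ships the published cohort-level model
(span 0.7235, k 0.2883 / day, plateau 0.2683) as `PUBLISHED_DECAY`; all
failure-to-decline thresholds and worked-example numbers derive from it
at run time, never from stored outputs.

## Failure to decline

The threshold at x days after the peak is f(x) plus an *additive* margin
of 15 percentage points of the peak — f(x) + 0.15, not f(x) × 1.15; only
the additive reading reproduces the published thresholds 72.30% (x = 3)
and 64.67% (x = 4). Assessment days default to x ∈ {3, 4}. The decision
is strict: observed > threshold ⇒ failure; equality passes.

Because draws are sparse, the observed value at an assessment day is
resolved as: exact-day draw; else nearest draw within ±1 day (earlier
day wins ties, preferring the more conservative earlier-higher value);
else linear interpolation between the bracketing draws; else the day is
unassessable and reported as non-failing with an explicit
`assessable=False` flag — an absent observation is evidence of nothing.

A note on day labels: the assessment days are *days after the
individual CRP maximum* (x = 3 and 4). Relative to the operation they
fall on calendar days 5–8 for a typical day-2–4 peak, which is why the
later assessment is often referred to as the "day 5" criterion in the
clinical shorthand carried by the feature name `failure_to_decline_d4`.

## Published scores

The three classifiers are fixed linear scores, shipped as JSON
resources and applied verbatim with the original integer encodings
(sex 1 = male / 2 = female; approach 1–6). Orientation is uniformly
"score > cut-off ⇒ infection". The "multinomial" model has a binary
outcome and therefore collapses to a single linear score; the name is
kept only in the identifier. The multinomial sex coefficient (−18.57)
makes sex nearly decisive — a shift of 18.57 between codes — which is
suspicious of a scaling artifact in the source; it is implemented as
printed and flagged here.

Refitting on new cohorts uses statsmodels maximum likelihood. Backward
elimination drops the term with the largest likelihood-ratio p-value
until all remaining terms have p < 0.10; this approximates, but does
not reproduce, SPSS's "backward conditional" selection. Cox–Snell
R² = 1 − exp(2(LL₀ − LLm)/n); Nagelkerke R² rescales it by its maximum.

## ROC

Thresholds are midpoints between consecutive sorted unique scores plus
±∞, so every achievable confusion table is visited once. The AUC is the
trapezoid over the (FPR, sensitivity) polyline, with vertices sorted
lexicographically so vertical segments keep their curve order (with
tied scores an unstable sort by FPR alone silently cuts corners). The
identity AUC = U/(n₁n₀) with midrank ties is implemented independently
(`auc_rank_statistic`) and the two agree to 1e−12 in the test suite.

## Multiplicity and group tests

Per-day comparisons use Welch's t-test (no equal-variance assumption)
on each calendar day with ≥ 2 observations per group; sparser days are
excluded from the family. The two-stage Benjamini–Krieger–Yekutieli
step-up runs Benjamini–Hochberg at α′ = α/(1+α), estimates the number
of true nulls m₀ = m − r₁, and reruns BH at α′·m/m₀ — the procedure's
standard definition, cross-checked against statsmodels' `fdr_tsbky`.
q-values are the smallest level at which each p-value is rejected,
found by bisection (the rejection set is monotone in the level);
Holm–Šidák is available as the family-wise alternative.

Under the global null the two-stage procedure leaves ~95% of simulated
cohorts with no significant day. When two strong effects are present
among ~15 tested days the *exact* recovery rate of the effect set is
~86%, not higher: stage 2 runs at α′·m/m₀ ≈ 0.055 and the smallest of
the ~13 null p-values slips under its rank-3 step-up threshold in ~13%
of families. This is the designed behavior of an adaptive FDR procedure,
and the test suite asserts exactly these calibrated rates.

Two-group covariate tests follow the conventional dispatch: Mann–Whitney
for continuous variables (exact enumeration when n₁·n₂ ≤ 400 and
tie-free, otherwise the tie-corrected normal approximation), Fisher's
exact (two-sided by the point-probability method) for 2×2 tables,
Pearson chi-square for larger tables.

## Sample size

The a-priori design computation treats the infection–CRP association as
a point-biserial correlation ρ and finds the smallest n whose t-test of
ρ = 0 (df = n − 2, noncentrality ρ/√(1−ρ²)·√n) reaches the requested
power, by doubling + bisection on the monotone power curve. Tails are
an explicit argument because the convention is consequential: at
ρ = 0.15, α = 0.05, power 0.95 the one-tailed design needs n = 472 and
the two-tailed ≈ 570. The one-tailed form is the default convention of
the common power-analysis software for this test.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, with
defaults matched to the published summary statistics: 708 patients,
infection prevalence 8/708; draw intervals ~ Normal(2.43, 0.92) days
clipped ≥ 1 and rounded; peak day ∈ {2, 3, 4} (mode 3); peak CRP
log-normal moment-matched to mean 97.60 / SD 60.95 mg/L (non-infected)
and 143.38 / 72.31 (infected); preoperative CRP log-normal
(13.07 / 25.90); multiplicative log-normal trajectory noise with
CV 0.15; covariates (age, BMI, sex, approach, trauma indication,
lengths of stay) drawn from the published per-group distributions.
Log-normals are the natural choice for CRP: the quantities are positive
and strongly right-skewed (cohort SDs are of the order of the means).

Latent trajectory: preoperative baseline; linear rise from day 0 to the
peak day; then peak · f(x)/f(0) — the decay curve rescaled so the
trajectory is continuous at the peak and its maximum equals the drawn
peak value, since that drawn value emulates the *observed*
postoperative maximum to which the summary statistics refer. Infected
patients additionally receive, with probability 0.5, a second-peak bump
(triangular, 3–5 days wide, centered ~ Normal(8.25, 3.20) truncated
≥ peak + 2, amplitude capped below the primary peak) and a late
elevation multiplier of 1.8 from day 10 onward. The multiplier is a
free default chosen so the late days (11/14) separate between groups;
it is not an estimate from data. Values are floored at 0.5 mg/L (assay
detection limit).

Two scheduling conventions matter for testability: the first
postoperative draw falls on day 1 or 2 (routine early labs), and the
schedule always contains the peak day — when the generated gaps miss
it, the nearest postoperative draw is snapped onto it, preserving the
draw count and hence the mean sampling interval. Without an observed
maximum, peak-normalization would align to an off-peak draw and even
noiseless cohorts could not reproduce the decay parameters exactly.

The approach-code weights printed in the source sum to 96.71%, not
100% (a defect of the published table); the generator keeps the printed
weights as defaults and renormalizes at draw time.

What the generator does *not* emulate: within-patient autocorrelated
noise (noise is i.i.d. per draw), covariate–trajectory correlations
beyond the infection label (age, BMI and approach do not shape the
curve), WBC/hemoglobin/platelet series, revision-censored follow-up,
and the empirical approach-group differences. Passing tests on
synthetic cohorts therefore demonstrate the *pipeline's* correctness
and calibration under the assumed structure, not clinical performance
on real patients; in particular the published cohort-level sensitivities,
specificities and AUCs depend on the original 708-patient dataset and
are not reproducible from simulation.

A deterministic eight-patient worked cohort
(`generate_worked_fixture`) encodes the published infected patients:
peaks (day, mg/L) of (11, 256.4), (6, 91.5), (6, 105.1), (6, 63.4),
(1, 139.1), (5, 74.6), (14, 203.2), (1, 213.7), published observations
placed exactly at the assessment days, monotone-declining filler
between peak and assessment (geometric interpolation) so no spurious
local peaks are manufactured, and patient 7's secondary peak at day 11
preceding its primary maximum at day 14.

## Problem sizes in the test suite

The suite is fully seeded. Parameter-recovery checks use 200 patients ×
11 aligned points × 20 seeds; AUC-identity checks 1,000 random score
sets; FDR oracle-equivalence 10,000 random p-vectors of length ≤ 20
(plus 300 hypothesis-driven cases); the FDR calibration simulations use
600 null cohorts and 50 effect cohorts of 52 patients each. The whole
suite runs in well under a minute on one CPU.

## Known limitations

* The decay model is fitted to *pooled* normalized points, weighting
  patients by their number of draws; a mixed-effects formulation would
  weight patients equally but is out of scope.
* `value_at_day_after_peak` interpolates linearly on an exponential
  curve; over a 2–4-day bracket this biases the resolved value slightly
  upward (conservative for failure-to-decline).
* Backward elimination is a greedy LR-test loop, not best-subset; with
  collinear features the retained set can differ from SPSS output.
* The exact Mann–Whitney path requires tie-free data; heavily tied
  small samples silently use the corrected normal approximation.
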