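# Methods

This note documents the models, rules, numerical choices and known
limitations behind the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Time model and eligibility

All windows are measured in hours from PICU admission and are closed
intervals: "within 12 h" is [0, 12], "within 24 h" is [0, 24], "within
3 days" is [0, 72]. Boundary cases therefore fall *inside* the window: a
patient first reaching KDIGO stage ≥ 2 at exactly 12.0 h is excluded as
early severe AKI, and a 47.9 h stay is a short stay.

The eligibility filter applies four exclusions in a fixed precedence
order, recording the first matching reason per patient: (1) hospital stay
< 48 h, (2) previously known kidney disease, (3) first AKI onset strictly
after 72 h, (4) severe AKI at or before 12 h. The source counts give
per-reason totals but no precedence; fixing the order makes the reason
partition of the excluded set well defined, which a property test checks.
Reason (3) needs the first onset over the *full* recorded series — the
72 h assessment clips onsets at 72 — so the filter accepts an optional
unclipped first-onset map computed by `kdigo.first_onset_any`; without
it, a patient with no AKI inside the window is simply eligible.

## Baseline creatinine and KDIGO staging

Baseline serum creatinine (SCr) is the lowest measured value in the
3 months before admission when available; otherwise it is back-calculated
from height via the bedside Schwartz formula at an assumed eGFR of
120 mL/min/1.73 m²: SCr[mg/dL] = k·height[cm]/120 with k = 0.413
(configurable; the bedside value is the modern pediatric standard), then
converted to µmol/L by 88.4. µmol/L is the canonical internal unit; the
absolute KDIGO cutoffs are pre-converted (0.3 mg/dL → 26.5 µmol/L,
4.0 mg/dL → 353.6 µmol/L).

Creatinine staging evaluates at each measurement time: stage 1 for
SCr/baseline in [1.5, 2.0) or an absolute rise ≥ 26.5 µmol/L between any
two measurements ≤ 48 h apart (brute-force over pairs — series are
short); stage 2 for [2.0, 3.0); stage 3 for ratio ≥ 3.0, SCr ≥ 353.6
µmol/L, or renal replacement therapy (RRT) initiated. Urine-output
staging converts interval volumes to mL/kg/h (an entry at offset *t*
covers the interval since the previous entry, the first starting at
admission) and credits a criterion at the instant its duration is
attained: < 0.5 sustained 6 h → stage 1, 12 h → stage 2; < 0.3 for 24 h
or anuria for 12 h → stage 3. The combined stage is the running maximum
over both routes; severe AKI is stage ≥ 2 within 72 h. Whether the
original analysis used urine criteria at all is not stated, so the urine
route is a switch (`kdigo.use_uo`, default on); removing it can never
raise a stage, which is property-tested. An empty creatinine series
stages 0 with a logged warning rather than failing.

## Fluid overload and the RAI

FO% = (Σ fluid in − Σ fluid out)[L] / admission weight[kg] × 100 over
[0, 24] by default. FO+ requires strictly > 10 % (a balance of exactly
10.000 % is FO−, the literal reading of the "> 10 %" definition). The
window is a parameter so the same operation can feed the RAI injury
stratum at 12 h; the source does not state which FO window enters the
12 h RAI, and the default uses the 24 h value (`rai.fo_window_h` to
change).

Risk tiers do not sum — the highest applicable tier applies (the printed
product range 1–40 forces max-of-tiers), and the injury score is the
maximum of the creatinine band and the FO band, the established
renal-angina convention for parallel injury columns. Band edges: the
creatinine bands are [≤1] → 1, (1, 1.5) → 2, [1.5, 2) → 4, [≥2] → 8
(closing the printed gap between "1.49×" and "1.5×" at 1.5); the FO bands
are (<5) → 1, [5, 10) → 2, [10, 15] → 4, (>15) → 8, honoring the printed
"> 15 %" top band, so exactly 15 % scores 4 and exactly 10 % scores 4.
With no creatinine measurement in the first 12 h the ratio defaults to
1.0 (no documented change). An exhaustive 3×4×4 enumeration confirms
RAI+ ⇔ RAI ≥ 8 across all tier combinations.

## Statistics

- **Odds ratios**: OR = ad/bc with 95 % Wald CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and a Wald-z p-value. Zero cells
  error unless the Haldane +0.5 correction is enabled. Wald (not
  profile-likelihood) intervals are used throughout because the reported
  intervals this package reproduces follow Wald arithmetic exactly.
- **Chi-square**: Pearson without continuity correction, falling back to
  Fisher's exact test when any expected count is strictly below 5 (the
  result records which test ran). A table with every expected count
  exactly 5 stays on the Pearson path.
- **Group comparisons**: two-sided Wilcoxon rank-sum with midrank ties
  and the normal approximation for skewed covariates; Student's t for
  symmetric ones; Kruskal–Wallis / one-way ANOVA across three strata.
  Identical samples return p = 1 with a warning.
- **Logistic regression** is authored in-package as Newton–Raphson IRLS:
  convergence at max |score| < 1e−8 or coefficient step < 1e−10 within 50
  iterations; Wald SEs from the inverse observed information; ORs and CIs
  by exponentiation. Non-convergence and separation (detected by
  diverging coefficient magnitudes, |β| > 15, under which the score
  equations can still be met numerically) yield a flagged fit with a
  diagnostic and a logged warning, never a silent result. Tests verify
  the saturated-model identity exp(β̂) = sample OR to 1e−6 and agreement
  with an independent reference implementation.
- **ROC/AUC**: the Mann–Whitney construction with case-control ties
  counted ½, curves swept over unique thresholds (positive at
  score ≥ threshold), CIs from the Hanley–McNeil variance. A binary test
  has the single interior vertex (1−specificity, sensitivity) and AUC =
  (sens + spec)/2; `auc_scores` on a binarized score reproduces it
  exactly (tested). AUC is invariant under strictly monotone transforms
  (property-tested). Constant scores give AUC 0.5 with a warning.
- **Youden cutoff**: the threshold maximizing sens + spec − 1 over the
  unique observed scores, ties broken toward the higher threshold.
- **Combined predictor**: logistic fit of outcome on {RAI+, lactate};
  the fitted linear predictor is the score. A constant covariate is
  dropped (with a warning), which makes the combined AUC degenerate to
  the remaining predictor's AUC.
- **Multivariable model**: the pre-specified set {early RAI+, early VS,
  serum lactate}; no stepwise selection (the original selection method is
  unstated). p-values are two-sided at 0.05 with no multiplicity
  adjustment. Report rendering rounds half-up to 2 decimals; internal
  computation is full precision.

Two printed-value discrepancies are documented rather than matched: the
binary-test closed form gives AUC 0.7056 for creatinine elevation and
0.5917 for FO+ where 0.70 and 0.58 were printed, and the severe-AKI
contrast in the RAI stratification table prints p = 0.04 where Pearson
chi-square on its own printed counts gives p < 0.01. The package reports
full-precision values.

## Synthetic cohorts

The generator emulates a 66-patient septic-shock PICU cohort at two
levels sharing one configuration.

**Indicator level.** A severe-AKI label ~ Bernoulli(36/66); indicators
{RAI+, SCr>base, FO+, MV, VS, RRT, death, sex, underlying disease} drawn
from their conditional frequencies given the label (defaults 30/36 vs
8/30, 28/36 vs 11/30, 9/36 vs 2/30, 28/36 vs 9/30, 29/36 vs 9/30, 13/36
vs 3/30, 25/36 vs 2/30, …). Indicators are conditionally independent
given the label — the maximum-entropy default when only margins are
known — with an optional Gaussian-copula correlation between RAI+ and
SCr>base, since creatinine elevation enters both definitions. Skewed
covariates (lactate, APTT, platelets, PRISM III, PELOD-2, age) are
log-normal with µ = ln median and σ = ln(q3/q1)/(2·z₀.₇₅), solved from
the per-group medians and IQRs (lactate medians 4.0 vs 2.8 mmol/L);
albumin is normal (30.38 ± 7.35 vs 33.92 ± 6.09 g/L). A two-parameter
log-normal cannot match a heavily asymmetric printed IQR (non-severe
platelets), so the median and quartile ratio are honored. The implied
population RAI+ odds ratio is ≈ 13.75 and the implied lactate
density-crossing cutoff is ≈ 4.7 mmol/L; both are recovered within
Monte-Carlo tolerance at n = 50,000 in the acceptance run.

**Trajectory level.** Each patient first receives an indicator draw,
then raw series constructed to realize it through the actual pipeline:
height/weight from age with biological noise; baseline either "measured"
(Schwartz value with noise, half the patients) or left to the pipeline's
Schwartz estimate; a piecewise-linear creatinine-ratio trajectory sampled
on a regular grid plus its own knot times (early 12 h ratio < 2 so no
eligible patient is early-severe; severe onsets uniform on (14, 66) h;
severe patients reach stage 3 with probability 31/36, non-severe reach
stage 1 with probability 17/30; stage-0 trajectories are capped below
every criterion including the 26.5 µmol/L rise rule); urine in 6 h bins
at 1.0–2.5 mL/kg/h, with an oliguric 0.32–0.45 mL/kg/h phase in 30 % of
severe patients (kept above the 0.3 stage-3 line so the urine route adds
signal without overriding the configured stage split); fluid bins
realizing the drawn FO+ flag exactly (FO+ uniform on 10.5–22 %, FO−
truncated normal below 9.5 %); MV/VS onsets before 10 h when flagged.
Two mechanical constraints depart from conditional independence: RRT
within the window implies KDIGO stage 3, so only stage-3-bound patients
start RRT inside 72 h (others — e.g. the fluid-overload indications seen
in non-severe patients — start after 72 h), and those late-RRT
non-severe patients are routed through the stage-1 arm so late RRT is
never misread as late-onset AKI. Exclusion archetypes (3 short-stay, 5
kidney-disease, 4 late-onset, 6 early-severe by default) are appended
with otherwise benign series.

All randomness flows from one `numpy` generator (default seed 20160101);
the same seed yields byte-identical CSV output. The generator reproduces
conditional frequencies, margins and the population odds structure, but
it does not model between-indicator dependence beyond the label (except
the knob and the two mechanical links above), mortality causality, or
PRISM/PELOD generation mechanisms (group-shifted noise only). Passing
tests on these cohorts therefore validate the pipeline's rules and
statistics, not the clinical joint distribution of real septic-shock
patients.

## Problem sizes and tolerances

The test suite and acceptance script use: exhaustive enumeration for the
tier algebra; 200 random positive-cell 2×2 tables for the logistic
identity and 500 random score vectors against the brute-force pairwise
AUC oracle; n = 50,000 indicator draws for law-of-large-numbers checks
(±0.01 on conditional frequencies, 10 % relative on the population OR);
n = 5,000 trajectory patients for pipeline-vs-generator consistency
(±0.03 on frequencies); n = 20,000 for multivariable odds-ratio recovery
(each coefficient within 3 estimated standard errors of its generating
value); and 25 replicate cohorts of 66 for cohort-scale Monte-Carlo
means. Replicates where a 66-patient draw is quasi-separated are skipped
in the combined-model average, as no finite ML fit exists there.

## Known limitations

- The urine-output interval convention (volume covers the gap since the
  previous entry) is an assumption; data recorded as instantaneous rates
  would need conversion upstream.
- The population lactate AUC implied by the configured log-normals is
  ≈ 0.63, below the 0.69 measured on the original patients — medians and
  IQRs alone under-determine the group separation.
- No eGFR-based pediatric stage-3 criterion, no AKI beyond 72 h (except
  the unclipped first-onset lookup for eligibility), no daily FO
  trajectories beyond the configured window, no survival modeling, no
  calibration or cross-validation of the combined model.
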