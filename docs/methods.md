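# Methods

## The phenotyping procedure

The pipeline classifies each patient in a fixed order.

1. **ESRD from codes.** Kidney-transplant or dialysis codes (diagnosis or
   procedure) short-circuit everything else: such patients are categorized
   as ESRD-after-transplant or ESRD-on-dialysis and receive no lab-based
   G/A stage. When both code sets appear, transplant wins by default
   (transplanted patients commonly carry historical dialysis codes); the
   `transplant_over_dialysis` switch flips this.
2. **Qualifying eGFR.** Every serum creatinine yields an eGFR (CKD-EPI 2009
   for ages ≥ 18 at the draw date, Bedside Schwartz below). An eGFR is
   *excluded* when any acute-kidney-injury, volume-depletion, or
   critical-illness code falls within ±`acute_window_days` (default 30)
   calendar days of it — a creatinine drawn off steady state says nothing
   about chronic function. The staging value is the most recent
   non-excluded eGFR.
3. **Chronicity.** An abnormality only counts as CKD when evidenced at
   least `chronicity_days` (default 90) before the staging value: a prior
   CKD diagnosis code, a prior non-excluded eGFR below 60, or a prior
   albuminuria-positive urine result. Under the default
   `strict_chronicity`, a prior eGFR must itself be abnormal; the looser
   reading (any prior qualifying value) is available because guidelines can
   be read either way, but a normal prior value is weak evidence of
   chronic disease.
4. **A-stage.** The urine test is chosen preference-first: albumin measures
   (UACR, 24-h albumin) over protein ratios (UPCR, 24-h protein, treated as
   numerically equal in mg/g vs mg/24 h) over dipstick-plus-specific-
   gravity. Direct measures use the KDIGO thresholds with ties at 300
   resolving to A2; indirect measures go through the fitted
   proportional-odds classifiers. An alternative `recency-first` policy
   (most recent test wins, tier breaks same-day ties) is provided because
   neither reading — a years-old gold-standard test versus yesterday's
   dipstick — is obviously right; preference-first is the default.
5. **Category.** G3a–G5 with chronicity is a CKD case (clinical stage
   3a–5); G1/G2 with chronic albuminuria or a CKD code is stage 1/2; G1
   patients (eGFR ≥ 90) with no CKD codes are G1A1 controls when the latest
   urine is A1, G1 controls when no urine exists; everyone else staged is
   `non_ckd_other`; no qualifying eGFR means `unstageable`. Patients at
   eGFR 60–89 without damage markers are deliberately *not* controls.

Staging is strictly at the most recent qualifying values: a patient whose
labs later normalize is staged by the current values, not by history.

## eGFR details

CKD-EPI 2009 with κ = 0.7 (F) / 0.9 (M), α = −0.329 / −0.411, the 1.018
female and 1.159 Black coefficients; the race term can be disabled
(`race_term`) in anticipation of race-free equations, and `race_black`
defaults to false when race is missing. The function is continuous at the
piecewise knot and strictly decreasing in creatinine; the synthetic
generator inverts it by bisection to a 1e-9 relative tolerance.

Pediatric staging needs a height concurrent with the creatinine. Heights
rarely coincide with blood draws, so the height at the draw date is taken
from the straight line through the two height observations nearest in time
(exact interpolation when they bracket the date, carry-forward for a single
observation). Equidistant candidates on opposite sides are preferred as a
bracketing pair; the line is clamped to the nearer observed height if
extrapolation would go non-positive, and heights older than
`max_height_gap_days` (default 730 — a local decision, not a guideline
value) are not carried.

## The albuminuria classifiers

The contributed statistical piece is a three-class cumulative-logit
(proportional-odds) model, P(Y ≤ k | x) = logistic(θ_k − β·x) with
θ1 < θ2. Features:

- UPCR model: log(max(UPCR, 1 mg/g)) — the floor keeps zero measurements
  finite and is far below clinically meaningful proteinuria.
- Dipstick models (one per reporting scale): the ordinal grade index and
  specific gravity as (SG − 1.000)×1000 ("milliunits", for numeric
  conditioning). Dilute urine with the same grade means more true
  albuminuria, so the fitted SG coefficient is negative.

Fitting maximizes the exact likelihood with an analytic gradient (BFGS),
enforcing θ1 < θ2 through θ2 = θ1 + e^δ. There is no regularization by
default; an optional ridge penalty on the slopes exists for separation
pathologies. Diverging parameter norms (no interior maximum — complete
separation) leave the capped fit flagged `converged: false`. Models
serialize to JSON with their feature spec, so a stored model is
self-describing and round-trips bit-exactly.

The two dipstick scales (negative/trace/1+..4+ and
negative/trace/10/30/100/300/≥300) are kept as distinct ordinal
vocabularies; Scale 2's "300" and "≥300" stay separate levels by default
(`merge_scale2_top` collapses them), and "trace" is always its own level.

Evaluation is seeded k-fold cross-validation (k = 10, unstratified by
default, `stratified` available): per-stage one-vs-rest accuracy,
sensitivity and specificity, each summarized as fold-mean ±
1.96·sd/√k. Two "squared error" summaries are reported side by side —
the fold-mean misclassification rate and the fold-mean squared
stage-distance — because both are defensible definitions for an ordinal
classifier and they answer different questions; neither is privileged.
A fold with no gold instances of a stage leaves that fold's sensitivity
undefined and excluded from the mean, with a warning.

## Comorbidity gradients

Patients with both stages known (ESRD and missing-urine patients excluded)
enter regressions of each comorbidity on the ordinal A- and G-scores with
age and sex as covariates: logistic for binary flags, Poisson for the
unique-code count, Wald tests per ordinal term, Bonferroni per-test alpha
= family alpha / (number of comorbidities × 2). Stages are coded as linear
integers (A1..A3 → 1..3, G1..G5 → 1..6 with the G3 split keeping its own
levels) — the simplest ordinal coding; orthogonal-polynomial contrasts
would be a reasonable alternative but are not implemented. Cell prevalences
are directly standardized to the U.S. 2000 standard population (19 age
bands, sexes weighted equally within a band); weights renormalize over the
strata present in a cell, and an empty cell is missing, never zero. The
shipped comorbidity dictionary is a small illustrative subset (diabetes,
hypertension, CHF, anemia, obesity); real analyses must supply their full
locally maintained code sets.

## The synthetic generator

`simulate_cohort` emulates the raw material the pipeline consumes, with
ground truth recorded per patient:

- a grid cell (A-stage × G-stage) drawn from a mixture (defaults put most
  mass at normal/mild disease, as in a mixed primary-care cohort), or ESRD
  with small probability (2% dialysis, 1% transplant);
- a constant true GFR inside the cell's band (edges padded half a unit so
  numeric inversion can never flip a stage at a boundary) and a true UACR
  inside the albuminuria band;
- six visits 120 days apart; at each visit a creatinine obtained by
  inverting CKD-EPI at the patient's age that day, times lognormal noise
  with CV 0.07 (a typical assay + biological within-person variability),
  and a UACR equal to the true value;
- AKI episodes (probability 0.15) multiply one visit's creatinine by 3 and
  emit an AKI code that day; CKD / dialysis / transplant codes are emitted
  with capture probability 0.9 (codes under-capture real conditions);
  15% of patients have no urine tests at all.

Truth labels are the direct staging rules applied to the noiseless true
values, so zero-noise recovery (CV 0, capture 1, no AKI) is an exact
end-to-end identity check of the pipeline's rule logic. All draws flow
from per-patient named substreams of one seed, so growing a cohort never
changes earlier patients.

`simulate_paired_urine` emulates the joint urine-test distribution through
a shared latent concentration factor c ~ lognormal(0, 0.5): UPCR = UACR +
lognormal non-albumin protein (mean 60 mg/g, log-sd 0.6), SG = 1.000 +
0.03·c capped at the physiologic 1.060, dipstick reading from UPCR·c on
mg/dL bins (Scale 1: 15/30/100/300/1000; Scale 2: 5/10/30/100/300/1000 —
standard urinalysis conventions adopted as generator constants). By
construction dipstick grade rises and SG rises with concentration at fixed
protein, which is what gives the fitted dipstick models their positive
grade and negative SG coefficients.

The generator inverts the same CKD-EPI implementation the pipeline uses.
That circularity is deliberate and acceptable: the recovery tests target
the rule logic and classifier training, while the equation itself is
checked against an independent closed-form oracle in the eGFR unit tests.
What passing synthetic tests do *not* show: performance on real EHR data,
where lab assays drift, codes are miscoded rather than merely missing,
urine tests cluster in sick patients, and true GFR trends over time. The
generator supports a GFR slope but defaults it to zero.

## Numerical and policy choices

- Calendar-day arithmetic everywhere; "one month" = 30 days; ages in
  years = days/365.25.
- Unit conversion happens once, at load (e.g. creatinine µmol/L ÷ 88.4);
  prefix code matching requires an explicit trailing `*` — implicit ICD
  prefixing is a silent-error source.
- Same-day duplicate creatinines are averaged; duplicate dipsticks keep the
  maximum grade.
- Argmax ties in classifier predictions resolve to the lower stage; direct
  thresholds resolve ties at 300 mg/g to A2.
- Problem sizes in the test suite and acceptance script (cohorts of
  200–500, 5000-row training sets, 1000 calibration replicates) were chosen
  as the smallest sizes at which the targeted properties are statistically
  decisive.

## Known limitations

- The shipped code dictionary and comorbidity groups are starter subsets;
  institution-specific code review is required before any real deployment.
- No CKD etiology (primary-disease) axis, no eGFR trajectory modeling, no
  cystatin-C or race-free eGFR equations (the race term can only be
  switched off).
- The A-stage classifiers are only as good as the paired training data;
  distribution shift in urine concentration or assay scales requires
  refitting.
- Sensitivity of case detection depends on longitudinal data density: a
  record spanning under 90 days can never satisfy chronicity and will not
  be called a case, by design.
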