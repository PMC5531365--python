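# Methods

## The measurement model

Item responses are modelled with the partial credit model (PCM), the
polytomous Rasch model of Masters.  For an item with step thresholds
δ₁ … δ_m (logits) and a person with measure θ (logits), the probability of
responding in category k ∈ {0 … m} is

    P_k(θ) = exp( Σ_{j≤k} (θ − δ_j) ) / Σ_h exp( Σ_{j≤h} (θ − δ_j) ),

the empty sum being 0.  With m = 1 this is exactly the dichotomous Rasch
model.  The Fisher information of an item at θ equals the model variance of
its category score, Σ k²P_k − (Σ kP_k)², which is also the slope of the item
characteristic curve dE[X|θ]/dθ; the test information function of an item
set is the pointwise sum of item informations.  Information curves are
evaluated on a θ grid from −6 to +6 logits in steps of 0.01 — wide enough to
cover the effective range of an 8-item screener, and finer than any reported
precision.

### Estimation

Joint maximum likelihood (JMLE): person measures and step thresholds are
estimated simultaneously by alternating damped per-parameter Newton–Raphson
updates.  Person measures solve the raw-score equations (observed raw score
= expected score); each threshold δ_ij solves its category-threshold score
equation (observed count of responses at-or-above step j = expected count).
Convergence requires the maximum absolute score residual below 0.01 and the
maximum parameter change below 0.001 logits, within 200 outer iterations;
Newton steps are clamped to ±1 logit for stability.  Identification: without
anchors the mean item location (mean of each item's thresholds, averaged
over items) is constrained to zero.  When persons are anchored (as in
diagnosis-anchored calibration) their measures are held exactly and no
centering is applied.

Degenerate cases are handled the standard JMLE way:

* **Extreme persons** (all-minimum or all-maximum observed responses) have
  no finite estimate; they are excluded from estimation and afterwards
  assigned the measure whose expected raw score lies 0.3 score units inside
  the boundary (an extrapolation convention shared by common Rasch
  software).
* **Unobserved categories**: an item category never used in the data makes
  its step inestimable; adjacent categories are collapsed for estimation and
  the raw→estimation category map is reported with the parameters.
* **No bias correction** is applied to the JMLE estimates.  JMLE thresholds
  are known to be inflated by a factor of roughly L/(L−1) for L items; with
  8 items and thresholds within ±2 logits this contributes ≈0.1–0.3 logits
  of RMSE at n = 500, which the parameter-recovery tests account for by
  using a well-targeted item set.  A correction flag is left to future work.

Fit is assessed by infit (information-weighted) and outfit (unweighted)
mean-square statistics of standardized residuals (expectation 1 under the
model), and by principal components analysis of the item-by-item correlation
matrix of standardized residuals ("first contrast"); cells where the model
variance is below 10⁻¹⁰ are excluded from fit statistics and counted.

## Item selection

Four methods nominate k-item short forms (k = 3 by default):

1. **Information-peak matching** ("test characteristic curve" method; the
   curve involved is conventionally called the test information function,
   and the traditional TCC name is kept only in report labels).  Among all
   C(8,3) = 56 subsets, select the one whose summed information peaks
   closest to the full form's peak location θ*; ties are broken by larger
   subset information at θ*, then by item order.  "Most closely matched" is
   ambiguous; the default reading is peak-location distance, and an
   alternative criterion (integrated absolute difference from the
   proportionally scaled full curve) is available behind a switch.
   Enumeration is exhaustive up to 12 items, greedy beyond.
2. **Diagnosis-anchored calibration** ("Rasch regression").  Every person's
   measure is anchored at their diagnosis value (0 or 1 logits — the
   dependent variable's own coding; a rescaling option exists), items are
   recalibrated, and ranked by |infit − 1| + |outfit − 1| ascending with the
   magnitude of the first-contrast loading as secondary criterion.  The
   composite ranking (fit first, residual PCA second) is this package's
   resolution of a procedure usually described without an explicit
   weighting; both criteria appear in the trace.  Under anchoring, an item
   fits exactly when its between-anchor logit difference equals the 1-logit
   anchor gap, so the method favours items whose discrimination matches the
   diagnosis split.
3. **Forward stepwise logistic regression** on raw item scores: entry by
   Rao score test (p < 0.05), removal by Wald, likelihood-ratio, or
   conditional test (p > 0.10).  The conditional criterion uses a one-step
   IRLS approximation of each reduced fit, the classical shortcut to a full
   refit.  Complete separation triggers an L2-penalized fallback
   (penalty 10⁻⁴), flagged in the trace.
4. **Stepwise discriminant analysis** minimizing Wilks' Λ with partial
   F-to-enter 3.84 and F-to-remove 2.71 (the defaults of the classical
   stepwise-DFA implementations).  Candidates producing a singular SSCP are
   skipped and logged.

All four are deterministic given the data.

## Classification metrics

Screen-positive means score ≥ cut throughout.  The 2×2 tables put diagnosis
truth in rows and screen classification in columns.  Kappa is unweighted
Cohen's kappa with marginal-product expected agreement; chi-square is the
Pearson statistic without continuity correction, reported with df = 1 (the
correct df for a 2×2 table; the report footer notes that such statistics are
sometimes printed with df = 2 elsewhere).  The empirical ROC uses every
distinct observed score plus one sentinel cut above the maximum; AUC is the
trapezoidal area, identical to the two-sample rank statistic with ties
counted ½.  The 95% AUC interval uses the Hanley–McNeil variance (screening
reports rarely state their CI method; this one is documented and
reproducible, and CI values are treated as descriptive only).  The optimal
cut maximizes Youden's J = se + sp − 100, ties resolved to the lowest cut
(favouring sensitivity, appropriate for screening).  Cronbach's alpha uses
unbiased variances after listwise deletion.  Report statistics are formatted
to two decimals, rounding half away from zero, matching how such tables are
conventionally printed.

## Synthetic cohorts

The generator emulates the structure every analysis stage assumes: one
latent trait θ ~ N(θ_mean, θ_sd) (default N(0,1)) drives both the 8 ordinal
item responses (PCM with per-item step thresholds) and the diagnostic
symptoms, each an independent Bernoulli with logit a·θ + b_s (slope a = 1.7,
the logistic≈probit scaling).  Diagnosis is "2 or more of 10–11 symptoms";
severity bands are 2–3 / 4–5 / ≥6 endorsed symptoms, the DSM-5 convention.
Given θ, items and symptoms are mutually independent.

Two built-in cohort specifications emulate the instrument's two development
samples: n = 207 with 10 symptoms and n = 369 with 11 symptoms.  Their
item-threshold locations and symptom-intercept ladders (equally spaced, gap
0.8) were calibrated offline by bisection over a Gauss–Hermite integral so
that, at large n, item endorsement margins (share responding ≥ 1) match the
published margins of those samples and diagnosis prevalence hits 47% / 46%.
The constants are frozen in `synth.py` and never refitted at run time.  A
published 100% endorsement margin is unattainable under a logistic link and
is targeted as 99.5%.

What the generator does **not** emulate: real item content and residual
multidimensionality, differential item functioning, missing-data mechanisms
(missingness must be injected explicitly), the heavier-than-binomial
symptom-count tail of real cohorts, and test–retest structure.  Passing
pipeline tests on synthetic cohorts therefore demonstrates correctness of
the computational chain under the stated model, not validity of the
instrument in any real population.

The instrument's raw scale is kept throughout scoring: items 1–7 score 0–4,
item 8 scores 0/2/4 (mapped to categories 0/1/2 for the PCM and mapped back
for totals), full-form total 0–32 with screening cut 13, short-form total
(items 3+5+6) 0–12 with cut 2.  A printed claim that totals "range from 1"
conflicts with the all-zero response; totals are implemented as 0–32.

## Pipeline

`run_study` executes, per cohort: exclusion rules (persons with incomplete
full-form totals, and optionally item-1 zero responders, leave the
agreement/ROC pool but stay in descriptives), descriptive statistics and
alpha, PCM calibration, the requested selection methods, ROC rows for the
full form (standard cut and Youden-optimal alternative cut) and for each
method's short form, agreement blocks (full-vs-diagnosis,
short-vs-diagnosis, short-vs-full), Spearman correlations, and — when
symptom counts are present — one-way ANOVA of short-form scores across
severity bands with η².  Exclusion bookkeeping is asserted internally
(persons in − exclusions = persons analyzed).  The report is a pure function
of config and inputs; JSON and markdown renderings are byte-deterministic.

## Problem sizes used in checks

Parameter recovery uses n = 500 (with n ∈ {200, 1000, 5000} for the
bias-trend check); generator calibration checks use n = 10⁴; the
short-vs-full AUC-gap property uses 20 replicate cohorts of n = 2000; the
end-to-end pipeline check runs the built-in n = 369 specification.  These
sizes give stable Monte-Carlo estimates for the tolerances asserted while
keeping the whole suite fast.
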