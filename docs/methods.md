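# Methods

## Problem and setting

A tertiary memory clinic evaluates patients with cognitive complaints
(subjective cognitive impairment, MCI, dementia; predominantly early-onset).
The reference standard for amyloid pathology is the CSF Aβ42/Aβ40 ratio,
dichotomized at an assay-specific cutoff; the question is how well cheaper,
routinely collected markers — MRI volumetry, atrophy rating scales,
neuropsychology, APOE4 — predict (a) amyloid positivity and (b) eligibility
for anti-amyloid antibody treatment. The package implements the full
analysis pipeline and, because patient-level data of this kind are not
freely distributable, a synthetic cohort generator that reproduces the
published group-level structure so that every stage is testable offline.

## Synthetic cohort model

One record per participant; 198 amyloid-negative and 92 amyloid-positive by
construction (fixed counts, not binomial draws — downstream prevalence
arithmetic of 92/290 is then exact). Conditional on group, each continuous
marker is Gaussian with the published group mean/SD, clipped to its valid
range; cognitive scores and visual rating scales are additionally rounded to
integers (MoCA/MMSE to [0,30], MTA to [0,4], GCA/PA/Fazekas to [0,3]).
Computed rating scales stay continuous at full precision — they are
software-estimated analogues of the visual scales and are reported on a
continuous scale; no fixed decimal precision is imposed. Binary markers
(sex, APOE4, anticoagulation, MRI availability) are Bernoulli per group;
diagnosis is categorical per group (67.1/19.1/13.6% SCI/MCI/dementia among
negatives, 22.8/25.0/52.2% among positives, derived from the published
counts 133/38/27 and 21/23/48).

**Key assumption: conditional independence.** Only group-wise marginals are
published, so markers are drawn independently given amyloid group. Real
markers are correlated within group (e.g. hippocampal volume with RAVLT), so
the synthetic composite-score AUC is an *independence-case* figure: with
four items of individual AUC ≈ 0.66–0.70, the four-item score reaches a
median AUC ≈ 0.80 over seeds (range ≈ 0.74–0.87 at n = 290), a band that
covers the published 0.82. Passing the synthetic end-to-end checks therefore
validates the pipeline's arithmetic and the generator's calibration, not the
real-data effect size of any marker combination.

**CSF ratio.** Per assay, a two-component Gaussian mixture on the ×10 ratio
scale, weight 0.317 on the low (amyloid-positive) component:
Innotest 0.317·N(0.42, 0.08²) + 0.683·N(0.95, 0.15²) and Lumipulse
0.317·N(0.63, 0.12²) + 0.683·N(1.30, 0.22²). Only the cutoffs (0.60 / 0.86)
and the prevalence are published; the component parameters were solved once
at design time so the weighted density crossings sit at those cutoffs
(0.601 / 0.860). Each record's ratio is rejection-sampled from its group's
component truncated at the assay cutoff, so group label and ratio can never
contradict. Records are assigned to Innotest vs Lumipulse with probability
0.5 each, approximating the even split implied by a mid-enrolment platform
change.

**Missingness** is completely at random, per variable, masking until the
observed N matches the published counts (education 267, MoCA 282, MMSE 232,
APOE4 280, RAVLT 254 at n = 290; scaled proportionally otherwise). Nothing
in the source data characterizes the real mechanism; MCAR is the neutral
choice and is verified by a pooled chi-square independence test in the
suite. `id` and the group label are never masked.

**Eligibility joint rate.** The published outcome is 45/290 eligible. The
generator has no joint-rate dial; eligibility emerges from the marginals:
~71 impaired positives × P(cognition in range) ≈ 0.81 × P(MRI) 0.95 ×
P(no anticoagulant) 0.90 ≈ 49 expected eligible. The MRI (0.95) and
anticoagulant (0.10) rates are not published and were chosen once as
clinically plausible values; observed counts land at 45–50 across seeds.

## Gaussian-mixture cutoffs

`fit_gmm` is a self-contained univariate EM: responsibilities via
log-sum-exp, closed-form M-step, variance floor 10⁻⁶ × sample variance
(guards component collapse), convergence when successive log-likelihoods
differ by < 10⁻⁸ (max 500 iterations), 5 restarts (first deterministic —
quantile blocks or 1-D k-means — the rest randomly initialized from data
points), best final log-likelihood wins. The per-iteration log-likelihood
trace is kept on the fit object and its monotonicity asserted in tests; the
implementation is cross-checked against scikit-learn's `GaussianMixture`,
which is never used as the implementation.

`derive_cutoff` solves w₁N(x|μ₁,σ₁²) = w₂N(x|μ₂,σ₂²) between the sorted
component means by bisection to 10⁻⁸ — the posterior-0.5 point, the standard
GMM dichotomization rule, always strictly between the means when a crossing
exists there. If no crossing lies between the means (extreme weight/variance
asymmetry) the quadratic log-density-difference is solved exactly and the
root nearest the lower mean returned with a warning. With equal variances
and weights this reduces to the midpoint. The rule is scale-equivariant.

At n = 290 the sampling noise of the fitted crossing has SD ≈ 0.02 on the
Innotest scale; single seeds can deviate up to ≈ 0.055 from the true
crossing (an independent EM implementation agrees to 4 decimals on those
seeds, so this is noise, not optimizer failure). Recovery checks therefore
bound the mean and median absolute error (≤ 0.03 over 50 seeds), not the
per-seed maximum.

## Diagnostic-accuracy toolkit

* **Empirical ROC**: one vertex per distinct value, ties collapsed (diagonal
  segments), anchors (0,0)/(1,1); direction "below"/"above" flips the score
  so higher = more disease-like. Trapezoidal area equals the Mann–Whitney
  estimator exactly; both routes are implemented and tested against an
  O(n²) pairwise oracle.
* **Operating-point reconstruction**: (sens, spec) rows → (1−sp, se)
  vertices plus anchors, sorted, trapezoid-integrated. For the complete
  threshold table of a discrete score this *is* the score's AUC — the
  identity behind reproducing the published composite-score AUCs from their
  printed rows alone.
* **Youden cutoffs**: exhaustive search over midpoints between consecutive
  distinct values plus ±∞; strict classification; ties in J break toward
  the rule classifying fewest records positive (most specific),
  deterministically. J is invariant under strictly monotone transforms.
* **DeLong inference**: placement values via midranks (V₁₀, V₀₁), variance
  S₁₀/m + S₀₁/n, Wald CI on the AUC scale truncated to [0,1] (a logit-scale
  variant behind `scale="logit"`); the paired test uses the 2×2 structural
  covariance and a two-sided normal p-value. Degenerate zero-variance
  differences (e.g. identical markers) return p = 1. Validated against
  bootstrap variance (within 15%), a label-preserving permutation test
  (within 0.02), 95% CI coverage and 5% type-I error simulations.
* **Analytic AUCs**: binormal Φ(Δμ/√(σ₊²+σ₋²)) (signed by direction) and
  Bernoulli (r₊ + 1 − r₋)/2 — used to cross-check published single-marker
  AUCs from published group summaries. The angular gyrus (0.696), RAVLT
  (0.683) and APOE4 (0.699) all reproduce the published 0.69 within 0.01;
  the hippocampus does **not** (binormal ≈ 0.66 vs published empirical
  0.68), consistent with non-Gaussian real volumes, and is deliberately
  excluded from analytic cross-checks.
* **Predictive values**: Bayes' rule on percent scales. The corner where no
  record tests positive (sens = 0, spec = 100) has no defined limit; it
  returns NaN with a warning rather than a conventional value.

Percentages are carried at full precision and rounded only in report
serialization (1 decimal for sens/spec/PPV/NPV, 3 for AUCs).

## Composite scores

Items are strict-inequality threshold rules plus the APOE4 binary item.
Default cutoffs are frozen to the published reference rules (hippocampus
< 6.94 ml, angular gyrus < 7.80 ml, RAVLT < 42); `rederive_cutoffs` switches
to Youden-derived cutoffs on the input cohort. Frozen is the default because
it makes results reproducible and comparable across cohorts. Region
selection averages left/right volumes before ranking candidates by
empirical AUC (ties alphabetical).

Scoring is complete-case: a record missing any item is dropped from that
score's evaluation, and the analysis subset's own prevalence feeds PPV/NPV.
Rationale: the per-variable observed Ns differ, and published predictive
values for the four-item model are only consistent with subset prevalences,
implying complete-case analyses upstream. Score evaluation asserts on every
run that sensitivity is non-increasing and specificity non-decreasing in
the threshold — a structural property of nested classification rules.

The ordinal score's AUC is computed directly by Mann–Whitney with a DeLong
CI. A binomial logistic regression with the score as sole predictor yields a
monotone transform of the score and hence the same ROC; the direct route is
used as the single-predictor equivalence makes the regression redundant.

## Eligibility engine

Criteria are independent toggles; failures accumulate as reasons
(`diagnosis`, `cognition`, `mri`, `anticoagulant`, `amyloid`,
`missing:<field>`), so relaxing any single criterion can only grow the
eligible set (asserted as a property test). MMSE governs when present —
"MoCA 17–30" is read as a fallback for a missing MMSE — configurable via
`mmse_governs`. The diagnosis criterion operationalizes "no evidence of
non-AD neurologic disorder" through an etiology-tag list (`FTD`, `vascular`
exclude an MCI diagnosis; dementia must carry an AD-type tag). Imaging
contraindications (microbleeds/ARIA risk) are not modeled: complete MRI
reports are not part of the record schema. Amyloid status is classified
from the ratio and assay via the cutoff rule, not read from the group
label.

## Pipeline and reporting

One root seed is split per stage via `SeedSequence`; stage outputs are pure
functions of inputs + config, making reruns byte-identical. Group
comparisons for imaging markers use an ANCOVA-style linear model
(marker ~ group + age + sex by default; the covariate set is configurable
and an empty set reduces exactly to the unadjusted comparison), demographics
use Kruskal–Wallis — both delegated to statsmodels/scipy. Report cells are
formatted "mean (± SD)"; every AUC in a report table is reproducible from
that table's own threshold rows (asserted in tests).

## Problem sizes

Defaults throughout match the reference conditions: cohorts of 290 (92
positive); 100 replicate cohorts for stochastic summaries; 50 seeds for GMM
recovery; 1,000/2,000 replicates for CI-coverage and type-I simulations;
2,000 bootstrap replicates and 5,000 permutations for the DeLong oracles.
The full suite runs in well under a minute on one CPU.

## Known limitations

* Conditional independence given group overstates the incremental value of
  correlated items and understates it for complementary ones; synthetic
  composite AUCs are calibration checks, not effect-size claims.
* The generator draws no within-record left/right volumes by default (the
  averaging path is exercised in tests via derived columns).
* Visual rating scales are modeled as clipped rounded Gaussians, which
  reproduces means/SDs but not necessarily full ordinal distributions.
* The MCAR missingness and the 0.5 assay split are modeling choices, not
  published facts.
* No cross-validation: like the original analysis, reported accuracies are
  apparent (in-sample) performance.
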