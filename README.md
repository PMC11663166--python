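# amypredict

Predicting CSF-amyloid status and anti-amyloid treatment eligibility from
markers that a tertiary memory clinic already collects: normalized regional
brain volumes, visual and software-computed atrophy rating scales, episodic
memory testing (RAVLT immediate recall) and APOE4 genotype.

Lumbar puncture and amyloid PET are the reference standards for amyloid
pathology, but both are expensive and hard to scale. A cheap pre-screen that
flags who is (un)likely to be amyloid-positive — and who might qualify for
anti-amyloid antibody treatment — helps clinics triage who needs the
invasive work-up. This package implements that screening pipeline as a
tested, reusable library plus an analysis layer:

* **Synthetic cohorts** (`amypredict.cohort`): a seeded generator emulating a
  memory-clinic population of 290 participants (92 amyloid-positive) with
  per-group Gaussian markers, per-group APOE4/diagnosis rates, per-assay CSF
  ratio mixtures and realistic per-variable missingness.
* **Data-driven CSF cutoffs** (`amypredict.gmm`): two-component Gaussian
  mixture fitted by EM to the Aβ42/Aβ40 ratio (×10 scale) per assay
  platform; the positivity cutoff is the weighted density crossing
  (posterior 0.5) between the component means. Frozen assay cutoffs:
  ratio < 0.60 (Innotest), < 0.86 (Lumipulse).
* **Diagnostic-accuracy toolkit** (`amypredict.roc`): empirical ROC curves,
  trapezoidal AUC (≡ Mann–Whitney), Youden-index-optimal cutoffs, DeLong
  standard errors / CIs / paired AUC tests, closed-form binormal and
  Bernoulli-marker AUCs, and Bayes PPV/NPV at any prevalence.
* **Composite scores** (`amypredict.score`): the two-region volumetric score
  (0–2: hippocampus < 6.94 ml, angular gyrus < 7.80 ml) and the four-item
  score (0–4: + RAVLT < 42 points, + APOE4 carriage), evaluated at every
  threshold with prevalence-adjusted predictive values.
* **Eligibility rule engine** (`amypredict.eligibility`): the five
  appropriate-use criteria — AD-type dementia or MCI without a non-AD
  neurologic disorder; MMSE 21–30 (MoCA 17–30 as fallback); MRI available;
  no anticoagulation; amyloid-positive CSF.
* **Pipeline + CLI** (`amypredict.pipeline`, `amypredict.cli`): one-command
  end-to-end run producing the full report-table bundle.

## The score in one formula

Each marker *m* is dichotomized at a reference cutoff *c\_m* chosen by the
Youden index (J = sensitivity + specificity − 1); one point is scored when
the value falls on the pathological side (strict inequality), plus one point
for APOE4 carriage:

    S = Σ_m 1[x_m < c_m] + 1[APOE4 carrier],   S ∈ {0, …, 4}

Classifying "S ≥ t" for t = 1..4 generates the operating points whose
polygon is the score's ROC curve; its trapezoidal area equals the
Mann–Whitney statistic P(S_pos > S_neg) + ½P(S_pos = S_neg). PPV/NPV follow
from Bayes' rule at the analysis prevalence.

## Worked example

```python
from amypredict import (default_config, generate_cohort, apply_missingness,
                        derive_assay_cutoffs, composite_score,
                        evaluate_thresholds, four_item_score_spec)

cfg = default_config()                      # the 198/92 reference conditions
cohort = generate_cohort(cfg, seed=7)
cohort = apply_missingness(cohort, cfg, seed=8)

cutoffs, fits = derive_assay_cutoffs(cohort, seed=1)
print(cutoffs.innotest_cutoff, cutoffs.lumipulse_cutoff)
# 0.5749424584327636 0.8594116720282521   (frozen references: 0.60 / 0.86)

spec = four_item_score_spec()
scores = composite_score(cohort, spec)      # NaN where any item is missing
ev = evaluate_thresholds(scores, cohort["amyloid_positive"], max_score=4)
print(ev.to_frame().to_string(index=False))
```

```
 threshold  sensitivity  specificity  ppv  npv                 auc
         1         98.7         20.0 35.5 97.1 0.807 (0.747-0.866)
         2         92.1         53.5 47.0 93.8
         3         60.5         84.1 63.0 82.7
         4         22.4         96.5 73.9 73.5
```

Read: at threshold ≥ 1 the four-item score misses almost no amyloid-positive
patient (sensitivity 98.7%, NPV 97.1% at this cohort's 31% prevalence), so a
score of 0 argues strongly against amyloid pathology; at ≥ 4 it is highly
specific (96.5%). The ordinal score's AUC here is 0.81 (DeLong 95% CI).

The same analysis as a shell pipeline:

```bash
amypredict simulate --seed 7 --out cohort.csv
amypredict cutoffs  --in cohort.csv --out cutoffs.json
amypredict score    --in cohort.csv --out scored.csv
amypredict evaluate --in scored.csv --max-score 4 --out table.csv
amypredict run      --seed 7 --out report/       # everything at once
```

The numbered drivers under `analysis/` tell the story end to end
(simulation → CSF cutoffs → single-marker accuracy → composite scores →
eligibility → full report) and write their tables under `results/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

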