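"""Published reference values from the development cohort.

A single memory-clinic development cohort (N = 290, 92 CSF-amyloid-positive)
underlies the default configuration of this package: per-group marker means
and standard deviations, APOE4 carrier rates, diagnosis mix, per-variable
observed counts, the frozen marker cutoffs, and the operating points
(sensitivity/specificity per score threshold) of the two composite scores.
These constants are the package's frozen defaults; everything downstream
(synthetic cohorts, score specs, accuracy arithmetic) is derived from them.

Scales and units: volumes are head-size-normalized millilitres; the CSF
Abeta42/Abeta40 ratio is carried on the x10 scale used by both assay
platforms; sensitivities/specificities are percentages.
"""

from __future__ import annotations

# Cohort composition
N_TOTAL = 290
N_POSITIVE = 92
N_NEGATIVE = 198
PREVALENCE_GLOBAL = N_POSITIVE / N_TOTAL

# Treatment-eligibility analysis: 45 of 290 met all five criteria
N_ELIGIBLE = 45
PREVALENCE_ELIGIBILITY = N_ELIGIBLE / N_TOTAL

# Per-group (negative, positive) mean and SD of the continuous markers
GROUP_STATS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((58.4, 7.1), (62.8, 5.8)),
    "education": ((13.7, 3.4), (13.6, 3.0)),
    "moca": ((23.4, 4.6), (20.3, 5.7)),
    "mmse": ((26.5, 3.9), (24.8, 4.5)),
    "ravlt_immediate": ((44.6, 12.7), (35.8, 13.4)),
    "hippocampus_ml": ((6.88, 0.95), (6.33, 0.92)),
    "angular_gyrus_ml": ((8.82, 1.11), (7.96, 1.26)),
    "visual_mta": ((0.74, 0.71), (0.97, 0.71)),
    "visual_pa": ((0.62, 0.70), (0.80, 0.70)),
    "visual_gca": ((0.86, 0.63), (1.17, 0.68)),
    "visual_fazekas": ((1.00, 0.70), (1.07, 0.63)),
    "computed_mta": ((0.45, 0.73), (0.82, 0.86)),
    "computed_pa": ((0.58, 0.78), (1.09, 0.90)),
    # the computed parietal GCA is reported with the same summary values as
    # the computed PA (the two labels refer to the same parietal estimate)
    "computed_gca_parietal": ((0.58, 0.78), (1.09, 0.90)),
    "computed_gca_frontal": ((0.68, 0.86), (1.17, 1.01)),
    "computed_gca_occipital": ((0.55, 0.73), (0.94, 0.82)),
    "computed_fazekas": ((0.68, 0.91), (0.68, 0.91)),
}

# Binary marker rates per group (negative, positive)
APOE4_RATES = (0.298, 0.696)
FEMALE_RATES = (0.585, 0.554)

# Diagnosis counts per group: (SCI, MCI, dementia)
DIAGNOSIS_COUNTS_NEGATIVE = (133, 38, 27)
DIAGNOSIS_COUNTS_POSITIVE = (21, 23, 48)

# Observed N per variable (all other variables are complete at N = 290)
OBSERVED_COUNTS = {
    "education": 267,
    "moca": 282,
    "mmse": 232,
    "apoe4_carrier": 280,
    "ravlt_immediate": 254,
}

# Assay-specific CSF Abeta42/Abeta40 positivity cutoffs (x10 scale);
# a ratio strictly below the cutoff is amyloid-positive
INNOTEST_CUTOFF = 0.60
LUMIPULSE_CUTOFF = 0.86

# Frozen Youden-optimal marker cutoffs from the development cohort
HIPPOCAMPUS_CUTOFF_ML = 6.94
ANGULAR_GYRUS_CUTOFF_ML = 7.80
RAVLT_CUTOFF = 42.0

# Operating points (sensitivity %, specificity %) per score threshold
# (thresholds >=1, >=2, ... in order), as reported for the development
# cohort, plus the AUCs reported alongside them.
VOLUMETRIC_GLOBAL_POINTS = [(86.9, 50.5), (38.0, 86.3)]
FOUR_ITEM_GLOBAL_POINTS = [(96.0, 27.0), (86.6, 67.6), (52.0, 91.7), (14.6, 96.4)]
VOLUMETRIC_ELIGIBILITY_POINTS = [(90.9, 43.7), (38.6, 81.9)]
FOUR_ITEM_ELIGIBILITY_POINTS = [(100.0, 23.9), (93.0, 57.8), (58.1, 85.1), (18.6, 95.6)]

REPORTED_AUCS = {
    "volumetric_global": 0.722,
    "four_item_global": 0.821,
    "volumetric_eligibility": 0.700,
    "four_item_eligibility": 0.818,
    "hippocampus": 0.68,
    "angular_gyrus": 0.69,
    "ravlt_immediate": 0.69,
    "apoe4": 0.69,
}
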