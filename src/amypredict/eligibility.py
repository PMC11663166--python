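"""Anti-amyloid treatment eligibility rule engine.

Five criteria, modeled on the appropriate-use recommendations issued after
the first anti-amyloid antibody approval:

1. clinical diagnosis of AD-type dementia, or MCI with no evidence of a
   non-AD neurologic disorder;
2. MMSE 21-30, or MoCA 17-30 when the MMSE is unavailable;
3. MRI available;
4. no anticoagulant treatment;
5. CSF profile consistent with AD (amyloid-positive Abeta42/Abeta40 ratio,
   classified against the assay-specific cutoff).

Failures are returned as reasons, never raised; a record missing a field a
criterion needs is ineligible with reason ``missing:<field>``.  When both
MMSE and MoCA are present and disagree, the MMSE governs (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from amypredict.gmm import AssayCutoffs, classify_amyloid
from amypredict.score import ScoreEvaluation, evaluate_thresholds

__all__ = [
    "EligibilityCriteria", "assess_eligibility", "eligibility_labels",
    "eligibility_evaluation",
]


@dataclass
class EligibilityCriteria:
    mmse_range: tuple[int, int] = (21, 30)
    moca_range: tuple[int, int] = (17, 30)
    require_mri: bool = True
    exclude_anticoagulant: bool = True
    require_amyloid_positive: bool = True
    require_diagnosis: bool = True
    require_cognition: bool = True
    #: etiology tags accepted as AD-type for a dementia diagnosis
    ad_dementia_etiologies: frozenset = frozenset({"AD-typical", "AD-atypical"})
    #: etiology tags counting as evidence of a non-AD neurologic disorder
    #: (excludes an MCI diagnosis)
    non_ad_neurologic: frozenset = frozenset({"FTD", "vascular"})
    #: when True, a present MMSE decides the cognitive criterion even if the
    #: MoCA disagrees; MoCA is only a fallback for a missing MMSE
    mmse_governs: bool = True
    cutoffs: AssayCutoffs = field(default_factory=AssayCutoffs)


def _missing(record, name) -> bool:
    return name not in record or pd.isna(record[name])


def assess_eligibility(record, criteria: EligibilityCriteria | None = None):
    """Evaluate one record against all enabled criteria.

    Returns ``(eligible, failed_criteria)``; every ineligible record carries
    at least one reason (``diagnosis``, ``cognition``, ``mri``,
    ``anticoagulant``, ``amyloid`` or ``missing:<field>``).
    """
    if criteria is None:
        criteria = EligibilityCriteria()
    reasons: list[str] = []

    if criteria.require_diagnosis:
        if _missing(record, "diagnosis"):
            reasons.append("missing:diagnosis")
        else:
            diag = record["diagnosis"]
            etio = None if _missing(record, "etiology_tag") else record["etiology_tag"]
            if diag == "dementia":
                if etio is not None and etio not in criteria.ad_dementia_etiologies:
                    reasons.append("diagnosis")
            elif diag == "MCI":
                if etio is not None and etio in criteria.non_ad_neurologic:
                    reasons.append("diagnosis")
            else:
                reasons.append("diagnosis")

    if criteria.require_cognition:
        mmse_lo, mmse_hi = criteria.mmse_range
        moca_lo, moca_hi = criteria.moca_range
        if not _missing(record, "mmse") and criteria.mmse_governs:
            if not mmse_lo <= record["mmse"] <= mmse_hi:
                reasons.append("cognition")
        elif not _missing(record, "moca"):
            if not moca_lo <= record["moca"] <= moca_hi:
                reasons.append("cognition")
        elif not _missing(record, "mmse"):
            if not mmse_lo <= record["mmse"] <= mmse_hi:
                reasons.append("cognition")
        else:
            reasons.append("missing:mmse")

    if criteria.require_mri:
        if _missing(record, "mri_available"):
            reasons.append("missing:mri_available")
        elif not record["mri_available"]:
            reasons.append("mri")

    if criteria.exclude_anticoagulant:
        if _missing(record, "anticoagulant"):
            reasons.append("missing:anticoagulant")
        elif record["anticoagulant"]:
            reasons.append("anticoagulant")

    if criteria.require_amyloid_positive:
        if _missing(record, "abeta_ratio"):
            reasons.append("missing:abeta_ratio")
        elif _missing(record, "csf_assay"):
            reasons.append("missing:csf_assay")
        elif not classify_amyloid(record["abeta_ratio"], record["csf_assay"],
                                  criteria.cutoffs):
            reasons.append("amyloid")

    return len(reasons) == 0, reasons


def eligibility_labels(cohort: pd.DataFrame,
                       criteria: EligibilityCriteria | None = None):
    """Per-record eligibility over a cohort table.

    Returns ``(eligible, reasons)``: a boolean Series and a Series of
    semicolon-joined failure reasons (empty string when eligible).
    """
    flags, reasons = [], []
    for _, rec in cohort.iterrows():
        ok, why = assess_eligibility(rec, criteria)
        flags.append(ok)
        reasons.append(";".join(why))
    return (pd.Series(flags, index=cohort.index, name="eligible"),
            pd.Series(reasons, index=cohort.index, name="failed_criteria"))


def eligibility_evaluation(cohort: pd.DataFrame, scores,
                           criteria: EligibilityCriteria | None = None,
                           max_score: int | None = None) -> ScoreEvaluation:
    """Accuracy of a score (or marker) at predicting treatment eligibility.

    Labels come from :func:`assess_eligibility`; thresholds, predictive
    values and AUC are computed exactly as for amyloid status, with
    prevalence = eligible / analysed records.
    """
    eligible, _ = eligibility_labels(cohort, criteria)
    if eligible.all() or not eligible.any():
        raise ValueError("eligibility labels are single-class; evaluation "
                         "is undefined")
    return evaluate_thresholds(scores, eligible, max_score=max_score)
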