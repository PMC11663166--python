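#!/usr/bin/env python
"""Composite point scores for amyloid status.

Scores every participant with the frozen two-region volumetric score (0-2)
and the four-item score (0-4, adding RAVLT immediate recall and APOE4), then
evaluates each threshold: sensitivity, specificity, prevalence-adjusted
PPV/NPV and the ordinal-score AUC with DeLong CI.  Also reproduces, by pure
arithmetic, the AUCs implied by the published threshold tables of the
development cohort.  Writes results/amyloid_<score>_evaluation.csv and
results/published_score_arithmetic.csv.
"""

from pathlib import Path

import pandas as pd

from amypredict import reference
from amypredict.cohort import read_cohort
from amypredict.roc import auc_from_operating_points, ppv_npv
from amypredict.score import (
    composite_score, evaluate_thresholds, four_item_score_spec,
    select_regions, volumetric_score_spec,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    y = cohort["amyloid_positive"].astype(bool)

    picked = select_regions(cohort, ["hippocampus_ml"], ["angular_gyrus_ml"])
    print(f"selected regions (medial temporal, cortical): {picked}")

    for spec in (volumetric_score_spec(), four_item_score_spec()):
        scores = composite_score(cohort, spec)
        ev = evaluate_thresholds(scores, y, max_score=spec.max_score)
        print(f"\n{spec.name} score (complete case n={ev.n}, "
              f"prevalence {100 * ev.prevalence:.1f}%):")
        print(ev.to_frame().to_string(index=False))
        ev.to_frame().to_csv(OUT / f"amyloid_{spec.name}_evaluation.csv",
                             index=False)

    # arithmetic consistency of the published development-cohort tables
    rows = []
    for name, points, prev in (
        ("volumetric_global", reference.VOLUMETRIC_GLOBAL_POINTS,
         reference.PREVALENCE_GLOBAL),
        ("four_item_global", reference.FOUR_ITEM_GLOBAL_POINTS,
         reference.PREVALENCE_GLOBAL),
        ("volumetric_eligibility", reference.VOLUMETRIC_ELIGIBILITY_POINTS,
         reference.PREVALENCE_ELIGIBILITY),
        ("four_item_eligibility", reference.FOUR_ITEM_ELIGIBILITY_POINTS,
         reference.PREVALENCE_ELIGIBILITY),
    ):
        auc = auc_from_operating_points(points)
        ppv1, npv1 = ppv_npv(*points[0], prev)
        rows.append({"table": name, "reconstructed_auc": round(auc, 3),
                     "reported_auc": reference.REPORTED_AUCS[name],
                     "ppv_ge1": round(ppv1, 1), "npv_ge1": round(npv1, 1)})
    arith = pd.DataFrame(rows)
    arith.to_csv(OUT / "published_score_arithmetic.csv", index=False)
    print("\npublished threshold-table arithmetic:")
    print(arith.to_string(index=False))


if __name__ == "__main__":
    main()
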