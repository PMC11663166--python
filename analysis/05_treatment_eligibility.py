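#!/usr/bin/env python
"""Anti-amyloid treatment eligibility: who qualifies, and can the composite
scores predict it?

Applies the five-criterion rule engine (diagnosis, MMSE/MoCA range, MRI,
no anticoagulation, amyloid-positive CSF) to every participant, summarizes
the failure reasons, and evaluates both composite scores against the
eligibility label.  Writes results/eligibility.csv and
results/eligibility_<score>_evaluation.csv.
"""

import collections
from pathlib import Path

import pandas as pd

from amypredict.cohort import read_cohort
from amypredict.eligibility import eligibility_labels
from amypredict.score import (
    composite_score, evaluate_thresholds, four_item_score_spec,
    volumetric_score_spec,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    flags, reasons = eligibility_labels(cohort)
    pd.DataFrame({"id": cohort["id"], "eligible": flags,
                  "failed_criteria": reasons}).to_csv(OUT / "eligibility.csv",
                                                      index=False)
    n = int(flags.sum())
    print(f"{n} of {len(cohort)} participants eligible "
          f"({100 * n / len(cohort):.1f}%)")
    counter = collections.Counter(
        r for rs in reasons[~flags] for r in rs.split(";"))
    print("failure reasons (a record may carry several):")
    for reason, count in counter.most_common():
        print(f"  {reason}: {count}")

    for spec in (volumetric_score_spec(), four_item_score_spec()):
        scores = composite_score(cohort, spec)
        ev = evaluate_thresholds(scores, flags, max_score=spec.max_score)
        print(f"\n{spec.name} score predicting eligibility "
              f"(n={ev.n}, prevalence {100 * ev.prevalence:.1f}%):")
        print(ev.to_frame().to_string(index=False))
        ev.to_frame().to_csv(OUT / f"eligibility_{spec.name}_evaluation.csv",
                             index=False)


if __name__ == "__main__":
    main()
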