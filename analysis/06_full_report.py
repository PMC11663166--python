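#!/usr/bin/env python
"""One-shot pipeline run: simulate, derive cutoffs, score, evaluate, report.

Equivalent to `amypredict run --seed 20260923 --out results/report`; kept as
a script so the whole analysis can be reproduced without the CLI.
"""

from pathlib import Path

from amypredict.pipeline import PipelineConfig, run_pipeline, write_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "report"


def main():
    bundle = run_pipeline(PipelineConfig(seed=20260923))
    write_bundle(bundle, OUT)
    print(f"cohort: {len(bundle.cohort)} records, "
          f"{bundle.n_eligible} treatment-eligible")
    print(f"GMM cutoffs: {bundle.gmm_cutoffs}")
    for name, ev in bundle.amyloid_evaluations.items():
        print(f"amyloid {name}: AUC {ev.auc.auc:.3f} "
              f"({ev.auc.ci_low:.3f}-{ev.auc.ci_high:.3f}), n={ev.n}")
    for name, ev in bundle.eligibility_evaluations.items():
        print(f"eligibility {name}: AUC {ev.auc.auc:.3f} "
              f"({ev.auc.ci_low:.3f}-{ev.auc.ci_high:.3f}), n={ev.n}")
    print(f"report tables under {OUT}")


if __name__ == "__main__":
    main()
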