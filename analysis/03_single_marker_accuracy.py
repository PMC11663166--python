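#!/usr/bin/env python
"""Single-marker accuracy for amyloid status.

For each volume, rating scale, cognitive test and APOE4: empirical AUC with
DeLong CI and the Youden-optimal cutoff.  Also compares visual vs computed
rating scales head-to-head with the paired DeLong test, and checks the
empirical volume/test AUCs against their closed-form binormal counterparts
computed from the configured group parameters.  Writes
results/marker_accuracy.csv and results/rating_scale_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from amypredict.cohort import default_config, read_cohort
from amypredict.pipeline import rating_scale_auc_comparison
from amypredict.roc import binary_marker_auc, binormal_auc, delong_auc_ci, youden_cutoff

OUT = Path(__file__).resolve().parent.parent / "results"

# marker -> direction (which side of the cutoff is disease-like)
MARKERS = {
    "hippocampus_ml": "below", "angular_gyrus_ml": "below",
    "ravlt_immediate": "below", "moca": "below", "mmse": "below",
    "visual_mta": "above", "computed_mta": "above",
    "visual_pa": "above", "computed_pa": "above",
    "visual_gca": "above", "computed_gca_frontal": "above",
    "computed_gca_occipital": "above",
    "visual_fazekas": "above", "computed_fazekas": "above",
}


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    y = cohort["amyloid_positive"].astype(bool)
    cfg = default_config()

    rows = []
    for marker, direction in MARKERS.items():
        vals = pd.to_numeric(cohort[marker], errors="coerce")
        ok = vals.notna()
        res = delong_auc_ci(vals[ok], y[ok], direction)
        rule = youden_cutoff(vals[ok], y[ok], direction, marker)
        spec = cfg.markers[marker]
        rows.append({
            "marker": marker, "direction": direction, "n": int(ok.sum()),
            "auc": round(res.auc, 3),
            "ci": f"{res.ci_low:.3f}-{res.ci_high:.3f}",
            "youden_cutoff": round(rule.cutoff, 3),
            "sens_at_cutoff": round(rule.sensitivity, 1),
            "spec_at_cutoff": round(rule.specificity, 1),
            "binormal_auc": round(binormal_auc(
                spec.mean_pos, spec.sd_pos, spec.mean_neg, spec.sd_neg,
                direction), 3),
        })
    apoe = cohort["apoe4_carrier"]
    ok = apoe.notna()
    res = delong_auc_ci(apoe[ok].astype(bool).astype(float), y[ok], "above")
    rows.append({
        "marker": "apoe4_carrier", "direction": "above", "n": int(ok.sum()),
        "auc": round(res.auc, 3), "ci": f"{res.ci_low:.3f}-{res.ci_high:.3f}",
        "youden_cutoff": float("nan"), "sens_at_cutoff": float("nan"),
        "spec_at_cutoff": float("nan"),
        "binormal_auc": round(binary_marker_auc(*reversed(
            cfg.rates["apoe4_carrier"])), 3),
    })
    acc = pd.DataFrame(rows).sort_values("auc", ascending=False)
    acc.to_csv(OUT / "marker_accuracy.csv", index=False)
    print(acc.to_string(index=False))

    comp = rating_scale_auc_comparison(cohort)
    comp.round(3).to_csv(OUT / "rating_scale_comparison.csv", index=False)
    print("\nvisual vs computed rating scales (paired DeLong):")
    print(comp.round(3).to_string(index=False))
    print(f"\nwrote {OUT / 'marker_accuracy.csv'} and "
          f"{OUT / 'rating_scale_comparison.csv'}")


if __name__ == "__main__":
    main()
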