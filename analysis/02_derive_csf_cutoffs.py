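#!/usr/bin/env python
"""Derive data-driven CSF amyloid-positivity cutoffs.

Fits a two-component Gaussian mixture to the Abeta42/Abeta40 ratio per assay
platform and takes the weighted density crossing as the positivity cutoff.
On the default synthetic cohort the crossings land near the frozen assay
cutoffs (0.60 Innotest, 0.86 Lumipulse) because the generator's mixtures
were configured so.  Writes results/csf_cutoffs.json.
"""

import json
from pathlib import Path

from amypredict.cohort import read_cohort
from amypredict.gmm import derive_assay_cutoffs

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = read_cohort(OUT / "cohort.csv")
    cutoffs, fits = derive_assay_cutoffs(cohort, seed=0)
    doc = {"innotest_cutoff": cutoffs.innotest_cutoff,
           "lumipulse_cutoff": cutoffs.lumipulse_cutoff,
           "direction": "below-cutoff-is-positive"}
    for assay, fit in fits.items():
        doc[f"{assay.lower()}_fit"] = {
            "weights": fit.weights.tolist(), "means": fit.means.tolist(),
            "sds": fit.sds.tolist(), "n_iter": fit.n_iter,
            "converged": fit.converged,
        }
        print(f"{assay}: components N({fit.means[0]:.3f}, {fit.sds[0]:.3f}) / "
              f"N({fit.means[1]:.3f}, {fit.sds[1]:.3f}), "
              f"weights {fit.weights.round(3).tolist()}")
    print(f"derived cutoffs: Innotest {cutoffs.innotest_cutoff:.3f}, "
          f"Lumipulse {cutoffs.lumipulse_cutoff:.3f}")
    with open(OUT / "csf_cutoffs.json", "w") as fh:
        json.dump(doc, fh, indent=2)
    print(f"wrote {OUT / 'csf_cutoffs.json'}")


if __name__ == "__main__":
    main()
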