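"""End-to-end orchestration and report tables.

``run_pipeline`` executes simulate (optional) -> CSF cutoffs -> composite
scores -> threshold evaluation -> eligibility -> report, deterministically
under one root seed that is split per stage.  The report bundle mirrors the
structure of a clinical diagnostic-accuracy paper: a cohort summary, a
group-comparison table for imaging markers, a per-marker AUC comparison of
visual vs computed rating scales with paired DeLong p-values, and
score-evaluation tables for amyloid status and treatment eligibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from amypredict.cohort import (
    CohortConfig, apply_missingness, default_config, generate_cohort,
    read_cohort, write_cohort,
)
from amypredict.eligibility import EligibilityCriteria, eligibility_labels
from amypredict.gmm import derive_assay_cutoffs
from amypredict.roc import delong_auc_ci, delong_paired_test
from amypredict.score import (
    CompositeScoreSpec, ScoreEvaluation, composite_score, evaluate_thresholds,
    four_item_score_spec, rederive_cutoffs, volumetric_score_spec,
)

logger = logging.getLogger("amypredict")

_version = "0.1.0"

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline",
           "group_comparison", "write_bundle"]


@dataclass
class PipelineConfig:
    """What to run: either simulate a cohort or load one from CSV."""

    cohort_csv: str | None = None
    simulate: bool = True
    cohort_config: CohortConfig = field(default_factory=default_config)
    with_missingness: bool = True
    #: "frozen" uses the published marker cutoffs; "rederive" searches the
    #: Youden-optimal cutoff per marker on the input cohort
    cutoff_mode: str = "frozen"
    #: re-derive the CSF assay cutoffs by GMM on the input cohort and use
    #: them for eligibility classification (otherwise the published assay
    #: cutoffs are used)
    gmm_cutoffs: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            doc = yaml.safe_load(text)
        cc = doc.pop("cohort_config", None)
        cfg = cls(**doc)
        if cc is not None:
            cfg.cohort_config = CohortConfig.from_dict(cc)
        return cfg

    def digest(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    cohort: pd.DataFrame
    cohort_summary: pd.DataFrame
    group_comparison: pd.DataFrame
    rating_scale_auc_comparison: pd.DataFrame
    score_specs: dict[str, CompositeScoreSpec]
    amyloid_evaluations: dict[str, ScoreEvaluation]
    eligibility_evaluations: dict[str, ScoreEvaluation]
    gmm_cutoffs: dict[str, float]
    n_eligible: int
    provenance: dict


def _split_seed(seed: int, n: int) -> list[int]:
    """Deterministically derive per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.2f} (± {x.std():.2f})"


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic/cognitive summary (mean (± SD) or %), with the
    observed N per variable and a rank-based p-value for group differences."""
    pos = cohort["amyloid_positive"].astype(bool)
    rows = []
    for var in ("age", "education", "moca", "mmse", "ravlt_immediate"):
        x = pd.to_numeric(cohort[var], errors="coerce")
        ok = x.notna()
        stat_p = kruskal(x[ok & ~pos], x[ok & pos]).pvalue if ok.sum() else np.nan
        rows.append({
            "variable": var, "n": int(ok.sum()),
            "negative": _fmt_mean_sd(x[ok & ~pos]),
            "positive": _fmt_mean_sd(x[ok & pos]),
            "p_value": float(stat_p),
        })
    for var, level in (("sex", "female"), ("apoe4_carrier", True)):
        col = cohort[var]
        ok = col.notna()
        frac_n = (col[ok & ~pos] == level).mean() * 100
        frac_p = (col[ok & pos] == level).mean() * 100
        rows.append({
            "variable": f"{var}={level}", "n": int(ok.sum()),
            "negative": f"{frac_n:.1f}%", "positive": f"{frac_p:.1f}%",
            "p_value": np.nan,
        })
    diag = cohort["diagnosis"]
    for level in ("SCI", "MCI", "dementia"):
        rows.append({
            "variable": f"diagnosis={level}", "n": int(diag.notna().sum()),
            "negative": f"{(diag[~pos] == level).mean() * 100:.1f}%",
            "positive": f"{(diag[pos] == level).mean() * 100:.1f}%",
            "p_value": np.nan,
        })
    return pd.DataFrame(rows)


def group_comparison(cohort: pd.DataFrame, markers,
                     adjust_for=("age", "sex")) -> pd.DataFrame:
    """Per-marker group means with covariate-adjusted p-values.

    Continuous imaging markers get an ANCOVA-style linear model
    (marker ~ group + covariates, via statsmodels OLS); with an empty
    adjustment set this reduces to the unadjusted two-group comparison.
    """
    import statsmodels.formula.api as smf

    pos = cohort["amyloid_positive"].astype(bool)
    rows = []
    for marker in markers:
        x = pd.to_numeric(cohort[marker], errors="coerce")
        if x.dropna().nunique() < 2:
            raise ValueError(f"marker {marker!r} is constant; no comparison")
        work = pd.DataFrame({"y": x, "group": pos.astype(int)})
        for cov in adjust_for:
            work[cov] = cohort[cov]
        work = work.dropna()
        terms = " + ".join(["group"] + [f"C({c})" if work[c].dtype == object
                                        else c for c in adjust_for])
        fit = smf.ols(f"y ~ {terms}", data=work).fit()
        rows.append({
            "marker": marker,
            "negative": _fmt_mean_sd(x[~pos].dropna()),
            "positive": _fmt_mean_sd(x[pos].dropna()),
            "p_value": float(fit.pvalues["group"]),
        })
    return pd.DataFrame(rows)


_RATING_PAIRS = [
    ("visual_mta", "computed_mta"),
    ("visual_pa", "computed_pa"),
    ("visual_gca", "computed_gca_frontal"),
    ("visual_fazekas", "computed_fazekas"),
]


def rating_scale_auc_comparison(cohort: pd.DataFrame,
                                pairs=_RATING_PAIRS) -> pd.DataFrame:
    """Visual vs computed rating-scale AUCs with paired DeLong p-values.

    Higher rating = more atrophy = more amyloid-like, so direction is
    "above" for every scale.
    """
    y = cohort["amyloid_positive"].astype(bool)
    rows = []
    for visual, computed in pairs:
        a = pd.to_numeric(cohort[visual], errors="coerce")
        b = pd.to_numeric(cohort[computed], errors="coerce")
        ok = a.notna() & b.notna()
        res_a = delong_auc_ci(a[ok], y[ok], "above")
        res_b = delong_auc_ci(b[ok], y[ok], "above")
        _, _, z, p = delong_paired_test(a[ok], b[ok], y[ok], ("above", "above"))
        rows.append({
            "visual_scale": visual, "computed_scale": computed,
            "auc_visual": res_a.auc, "ci_visual":
                f"{res_a.ci_low:.3f}-{res_a.ci_high:.3f}",
            "auc_computed": res_b.auc, "ci_computed":
                f"{res_b.ci_low:.3f}-{res_b.ci_high:.3f}",
            "delong_p": p,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | str | Path) -> ReportBundle:
    """Execute the full analysis and assemble the report bundle."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    t0 = time.time()
    seeds = _split_seed(config.seed, 4)

    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
        logger.info("loaded cohort: %d records from %s", len(cohort),
                    config.cohort_csv)
    elif config.simulate:
        cohort = generate_cohort(config.cohort_config, seeds[0])
        if config.with_missingness:
            cohort = apply_missingness(cohort, config.cohort_config, seeds[1])
        logger.info("simulated cohort: %d records (%d amyloid-positive)",
                    len(cohort), int(cohort["amyloid_positive"].sum()))
    else:
        raise ValueError("config must reference a cohort CSV or enable "
                         "simulation")

    # stage: CSF cutoffs
    criteria = EligibilityCriteria()
    gmm_cut: dict[str, float] = {}
    if config.gmm_cutoffs:
        cutoffs, _fits = derive_assay_cutoffs(cohort, seed=seeds[2])
        criteria = EligibilityCriteria(cutoffs=cutoffs)
        gmm_cut = {"Innotest": cutoffs.innotest_cutoff,
                   "Lumipulse": cutoffs.lumipulse_cutoff}
        logger.info("GMM assay cutoffs: %s", gmm_cut)

    # stage: scores
    specs = {"volumetric": volumetric_score_spec(),
             "four_item": four_item_score_spec()}
    if config.cutoff_mode == "rederive":
        specs = {k: rederive_cutoffs(cohort, v) for k, v in specs.items()}
    elif config.cutoff_mode != "frozen":
        raise ValueError(f"unknown cutoff_mode {config.cutoff_mode!r}")

    labels = cohort["amyloid_positive"].astype(bool)
    amyloid_evals, scores = {}, {}
    for name, spec in specs.items():
        sc = composite_score(cohort, spec)
        scores[name] = sc
        amyloid_evals[name] = evaluate_thresholds(sc, labels,
                                                  max_score=spec.max_score)
        logger.info("score %s: n=%d, AUC=%.3f", name,
                    amyloid_evals[name].n, amyloid_evals[name].auc.auc)

    # stage: eligibility
    eligible, reasons = eligibility_labels(cohort, criteria)
    cohort = cohort.assign(eligible=eligible, failed_criteria=reasons)
    elig_evals = {}
    for name, spec in specs.items():
        elig_evals[name] = evaluate_thresholds(scores[name], eligible,
                                               max_score=spec.max_score)
    logger.info("eligibility: %d of %d records eligible",
                int(eligible.sum()), len(cohort))

    imaging_markers = ["hippocampus_ml", "angular_gyrus_ml", "visual_mta",
                       "computed_mta", "visual_pa", "computed_pa",
                       "visual_gca", "computed_gca_frontal",
                       "computed_gca_occipital", "visual_fazekas",
                       "computed_fazekas"]
    bundle = ReportBundle(
        cohort=cohort,
        cohort_summary=cohort_summary(cohort),
        group_comparison=group_comparison(cohort, imaging_markers),
        rating_scale_auc_comparison=rating_scale_auc_comparison(cohort),
        score_specs=specs,
        amyloid_evaluations=amyloid_evals,
        eligibility_evaluations=elig_evals,
        gmm_cutoffs=gmm_cut,
        n_eligible=int(eligible.sum()),
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": _version,
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    logger.info("pipeline complete in %.2fs", time.time() - t0)
    return bundle


def write_bundle(bundle: ReportBundle, outdir) -> None:
    """Serialize every bundle table as CSV plus a provenance JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle.cohort.drop(columns=["eligible", "failed_criteria"]),
                 out / "cohort.csv")
    bundle.cohort[["id", "eligible", "failed_criteria"]].to_csv(
        out / "eligibility.csv", index=False)
    bundle.cohort_summary.to_csv(out / "cohort_summary.csv", index=False)
    bundle.group_comparison.to_csv(out / "group_comparison.csv", index=False)
    bundle.rating_scale_auc_comparison.to_csv(
        out / "rating_scale_auc_comparison.csv", index=False)
    for name, ev in bundle.amyloid_evaluations.items():
        ev.to_frame().to_csv(out / f"amyloid_{name}_evaluation.csv", index=False)
    for name, ev in bundle.eligibility_evaluations.items():
        ev.to_frame().to_csv(out / f"eligibility_{name}_evaluation.csv",
                             index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle.provenance | {"gmm_cutoffs": bundle.gmm_cutoffs,
                                       "n_eligible": bundle.n_eligible},
                  fh, indent=2)
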