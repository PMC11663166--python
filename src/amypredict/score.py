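"""Composite point scores from dichotomized markers.

Two default scores are provided, mirroring the development cohort's frozen
rules:

* volumetric score (0-2): hippocampus < 6.94 ml, angular gyrus < 7.80 ml;
* four-item score (0-4): the two volumes plus RAVLT immediate recall
  < 42 points and APOE4 carriage.

One point per satisfied rule, strict inequality at the cutoff.  Scoring is
complete-case: a record missing any item value gets a missing score and is
dropped from evaluations, whose PPV/NPV then use the analysis subset's own
prevalence.  Cutoffs may alternatively be re-derived on the input cohort by
Youden-index search (:func:`rederive_cutoffs`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from amypredict import reference
from amypredict.roc import (
    AUCResult,
    delong_auc_ci,
    mann_whitney_auc,
    ppv_npv,
    youden_cutoff,
)

__all__ = [
    "ScoreItem", "CompositeScoreSpec", "ScoreEvaluation",
    "volumetric_score_spec", "four_item_score_spec",
    "composite_score", "select_regions", "candidate_aucs",
    "rederive_cutoffs", "evaluate_thresholds",
]


@dataclass(frozen=True)
class ScoreItem:
    """One score item: a threshold rule on a continuous marker, or a binary
    marker scoring a point when truthy (APOE4 carriage)."""

    marker: str
    kind: str = "threshold"  # "threshold" | "binary"
    direction: str = "below"
    cutoff: float | None = None

    def __post_init__(self):
        if self.kind not in ("threshold", "binary"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == "threshold" and self.cutoff is None:
            raise ValueError(f"threshold item {self.marker!r} needs a cutoff")


@dataclass(frozen=True)
class CompositeScoreSpec:
    name: str
    items: tuple[ScoreItem, ...]

    def __post_init__(self):
        if not 1 <= len(self.items) <= 8:
            raise ValueError("a score spec holds between 1 and 8 items")
        markers = [it.marker for it in self.items]
        if len(set(markers)) != len(markers):
            raise ValueError("each marker may appear at most once")

    @property
    def max_score(self) -> int:
        return len(self.items)

    def to_json(self, path) -> None:
        doc = {"name": self.name,
               "items": [vars(it) | {} for it in self.items]}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CompositeScoreSpec":
        doc = json.load(open(path))
        return cls(doc["name"], tuple(ScoreItem(**it) for it in doc["items"]))


def volumetric_score_spec() -> CompositeScoreSpec:
    """The two-region volumetric score (0-2)."""
    return CompositeScoreSpec("volumetric", (
        ScoreItem("hippocampus_ml", cutoff=reference.HIPPOCAMPUS_CUTOFF_ML),
        ScoreItem("angular_gyrus_ml", cutoff=reference.ANGULAR_GYRUS_CUTOFF_ML),
    ))


def four_item_score_spec() -> CompositeScoreSpec:
    """The four-item score (0-4): volumes + RAVLT + APOE4."""
    return CompositeScoreSpec("four_item", (
        ScoreItem("hippocampus_ml", cutoff=reference.HIPPOCAMPUS_CUTOFF_ML),
        ScoreItem("angular_gyrus_ml", cutoff=reference.ANGULAR_GYRUS_CUTOFF_ML),
        ScoreItem("ravlt_immediate", cutoff=reference.RAVLT_CUTOFF),
        ScoreItem("apoe4_carrier", kind="binary"),
    ))


def composite_score(records, spec: CompositeScoreSpec) -> pd.Series:
    """Sum of satisfied rules per record; NaN where any item is missing.

    Accepts a DataFrame (returns a float Series aligned to its index) or a
    single mapping/Series (returns a scalar).
    """
    single = not isinstance(records, pd.DataFrame)
    df = pd.DataFrame([records]) if single else records
    total = pd.Series(0.0, index=df.index)
    complete = pd.Series(True, index=df.index)
    for item in spec.items:
        if item.marker not in df.columns:
            raise KeyError(f"marker column {item.marker!r} absent from records")
        col = df[item.marker]
        present = col.notna()
        complete &= present
        if item.kind == "binary":
            pts = col.eq(True).astype(float)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            if item.direction == "below":
                pts = (vals < item.cutoff).astype(float)
            else:
                pts = (vals > item.cutoff).astype(float)
        total += pts
    total[~complete] = np.nan
    if single:
        v = total.iloc[0]
        return float(v) if np.isfinite(v) else np.nan
    return total


def _averaged_volume(cohort: pd.DataFrame, name: str) -> pd.Series:
    """Average left/right variants when both exist, else the plain column."""
    left, right = f"{name}_left", f"{name}_right"
    if left in cohort.columns and right in cohort.columns:
        return (pd.to_numeric(cohort[left], errors="coerce")
                + pd.to_numeric(cohort[right], errors="coerce")) / 2.0
    if name in cohort.columns:
        return pd.to_numeric(cohort[name], errors="coerce")
    raise KeyError(f"no volume column(s) for candidate {name!r}")


def candidate_aucs(cohort: pd.DataFrame, candidates,
                   label_column: str = "amyloid_positive",
                   direction: str = "below") -> dict[str, float]:
    """Complete-case Mann-Whitney AUC of each candidate volume vs the label."""
    out = {}
    labels = cohort[label_column].astype(bool)
    for name in candidates:
        vals = _averaged_volume(cohort, name)
        ok = vals.notna()
        out[name] = mann_whitney_auc(vals[ok], labels[ok], direction)
    return out


def select_regions(cohort: pd.DataFrame, medial_temporal_candidates,
                   cortical_candidates,
                   label_column: str = "amyloid_positive") -> tuple[str, str]:
    """Pick the most accurate medial-temporal and cortical volumes.

    Left/right variants are averaged before ranking; the candidate with the
    highest empirical AUC against amyloid status wins in each group, ties
    broken alphabetically.
    """
    picks = []
    for cands in (medial_temporal_candidates, cortical_candidates):
        cands = list(cands)
        if not cands:
            raise ValueError("candidate region sets must be non-empty")
        aucs = candidate_aucs(cohort, cands, label_column)
        best = sorted(aucs.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        picks.append(best)
    return picks[0], picks[1]


def rederive_cutoffs(cohort: pd.DataFrame, spec: CompositeScoreSpec,
                     label_column: str = "amyloid_positive") -> CompositeScoreSpec:
    """Replace each threshold item's cutoff with the Youden-optimal cutoff
    derived on this cohort (complete-case per marker); binary items pass
    through unchanged."""
    labels = cohort[label_column].astype(bool)
    new_items = []
    for item in spec.items:
        if item.kind == "binary":
            new_items.append(item)
            continue
        vals = pd.to_numeric(cohort[item.marker], errors="coerce")
        ok = vals.notna()
        rule = youden_cutoff(vals[ok], labels[ok], item.direction, item.marker)
        new_items.append(replace(item, cutoff=rule.cutoff))
    return CompositeScoreSpec(spec.name, tuple(new_items))


@dataclass
class ScoreEvaluation:
    """Per-threshold accuracy of an ordinal score plus its AUC.

    ``table`` has one row per threshold (score >= t is test-positive) with
    percent sensitivity/specificity/PPV/NPV; sensitivity is non-increasing
    and specificity non-decreasing in t by construction.
    """

    table: pd.DataFrame
    auc: AUCResult
    n: int
    n_positive: int
    prevalence: float

    def operating_points(self):
        return list(zip(self.table["sensitivity"], self.table["specificity"]))

    def to_frame(self, decimals: int = 1, auc_decimals: int = 3) -> pd.DataFrame:
        """Report-style table: rounded percents, AUC and CI on the top row."""
        out = self.table.round(decimals)
        out["auc"] = ""
        out.loc[out.index[0], "auc"] = (
            f"{self.auc.auc:.{auc_decimals}f} "
            f"({self.auc.ci_low:.{auc_decimals}f}-{self.auc.ci_high:.{auc_decimals}f})"
        )
        return out


def evaluate_thresholds(scores, labels, max_score: int | None = None,
                        prevalence: float | None = None,
                        alpha: float = 0.05) -> ScoreEvaluation:
    """Evaluate an integer score at every threshold >= 1 .. >= k.

    Records with a missing score are dropped (complete-case) and the
    remaining subset's own prevalence feeds PPV/NPV unless an explicit
    ``prevalence`` is given.  The AUC is the ordinal score's Mann-Whitney
    estimate with a DeLong confidence interval.
    """
    s = pd.to_numeric(pd.Series(scores).reset_index(drop=True), errors="coerce")
    y = pd.Series(labels).reset_index(drop=True).astype(bool)
    keep = s.notna()
    s, y = s[keep].to_numpy(), y[keep].to_numpy()
    if not np.allclose(s, np.rint(s)):
        raise ValueError("scores must be integers (or missing)")
    s = s.astype(int)
    if y.all() or not y.any():
        raise ValueError("both classes must be present after dropping "
                         "incomplete records")
    k = int(max_score) if max_score is not None else int(s.max())
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    prev = prevalence if prevalence is not None else n_pos / (n_pos + n_neg)

    rows = []
    for t in range(1, k + 1):
        pred = s >= t
        sens = 100.0 * (pred & y).sum() / n_pos
        spec = 100.0 * (~pred & ~y).sum() / n_neg
        ppv, npv = ppv_npv(sens, spec, prev)
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec,
                     "ppv": ppv, "npv": npv})
    table = pd.DataFrame(rows)
    assert (np.diff(table["sensitivity"]) <= 1e-9).all(), \
        "sensitivity must be non-increasing across thresholds"
    assert (np.diff(table["specificity"]) >= -1e-9).all(), \
        "specificity must be non-decreasing across thresholds"
    auc = delong_auc_ci(s, y, "above", alpha=alpha)
    return ScoreEvaluation(table=table, auc=auc, n=len(s), n_positive=n_pos,
                           prevalence=prev)
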