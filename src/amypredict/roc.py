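"""Diagnostic-accuracy numerics.

ROC construction and trapezoidal AUC (identical to the Mann-Whitney
estimator), Youden-optimal dichotomization, DeLong placement-value variance,
confidence intervals and paired AUC comparison, analytic AUCs for Gaussian
and Bernoulli markers, and prevalence-adjusted predictive values.

Direction conventions: every operation takes ``direction`` as "above"
(higher marker value = more disease-like) or "below" (lower value = more
disease-like; the case for brain volumes, cognitive scores and the CSF
ratio).  Sensitivities, specificities, PPV and NPV are carried as
percentages; AUCs as proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ROCCurve", "AUCResult", "DichotomizationRule",
    "empirical_roc", "trapezoid_auc", "mann_whitney_auc",
    "auc_from_operating_points", "youden_cutoff",
    "delong_auc_ci", "delong_paired_test",
    "binormal_auc", "binary_marker_auc", "ppv_npv",
]

_DIRECTIONS = {"above", "below"}


def _check_direction(direction: str) -> str:
    d = direction.split("-")[0]
    if d not in _DIRECTIONS:
        raise ValueError(
            f"direction must be 'above' or 'below' (-is-positive), got {direction!r}"
        )
    return d


def _as_scores(values, direction: str) -> np.ndarray:
    """Orient values so that higher score = more likely positive."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("marker values must be finite")
    return -v if _check_direction(direction) == "below" else v


def _split(values, labels):
    y = np.asarray(labels, dtype=bool)
    v = np.asarray(values, dtype=float)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return v, y


@dataclass
class ROCCurve:
    """Empirical ROC polygon.

    ``fpr``/``tpr`` include the anchors (0,0) and (1,1); ``thresholds`` holds
    the marker cutoff attached to each vertex (+/-inf at the anchors, on the
    original marker scale).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class AUCResult:
    auc: float
    standard_error: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


@dataclass
class DichotomizationRule:
    """A single-marker decision rule: positive iff the value is strictly on
    ``direction``'s side of ``cutoff``."""

    marker: str
    direction: str
    cutoff: float
    youden_j: float = np.nan
    sensitivity: float = np.nan  # percent
    specificity: float = np.nan  # percent

    def applies(self, value):
        value = np.asarray(value, dtype=float)
        if _check_direction(self.direction) == "below":
            return value < self.cutoff
        return value > self.cutoff


def empirical_roc(values, labels, direction: str = "above") -> ROCCurve:
    """Empirical ROC curve with one vertex per distinct marker value.

    Ties collapse to a single vertex, producing diagonal segments.
    """
    v, y = _split(values, labels)
    s = _as_scores(v, direction)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    # vertex after each run of tied scores
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(~y_sorted)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thr_scores = np.r_[np.inf, s_sorted[idx]]
    # back to the original marker scale
    if _check_direction(direction) == "below":
        thr = -thr_scores
    else:
        thr = thr_scores
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def trapezoid_auc(curve: ROCCurve) -> float:
    """Area under the ROC polygon (trapezoidal rule)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def mann_whitney_auc(values, labels, direction: str = "above") -> float:
    """P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) via midranks."""
    v, y = _split(values, labels)
    s = _as_scores(v, direction)
    r = rankdata(s)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_from_operating_points(points) -> float:
    """AUC of the ROC polygon through given (sensitivity %, specificity %)
    operating points, anchored at (0,0) and (1,1).

    For the complete threshold table of a discrete score this reproduces the
    score's empirical AUC exactly.
    """
    pts = list(points)
    if len(pts) == 0:
        raise ValueError("at least one operating point is required")
    fpr, tpr = [0.0, 1.0], [0.0, 1.0]
    for sens, spec in pts:
        if not (0 <= sens <= 100 and 0 <= spec <= 100):
            raise ValueError(f"operating point outside [0, 100]: {(sens, spec)}")
        fpr.append(1 - spec / 100.0)
        tpr.append(sens / 100.0)
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))


def youden_cutoff(values, labels, direction: str = "below",
                  marker: str = "") -> DichotomizationRule:
    """Cutoff maximizing the Youden index J = sens + spec - 1.

    Candidates are the midpoints between consecutive distinct observed values
    plus -inf/+inf; classification is strict.  Ties in J break toward the
    cutoff classifying fewer records as positive (most specific rule),
    deterministically.
    """
    v, y = _split(values, labels)
    d = _check_direction(direction)
    u = np.unique(v)
    candidates = np.r_[-np.inf, (u[:-1] + u[1:]) / 2.0, np.inf]
    pos_sorted = np.sort(v[y])
    neg_sorted = np.sort(v[~y])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    if d == "below":
        # positive iff value < c
        tp = np.searchsorted(pos_sorted, candidates, side="left")
        fp = np.searchsorted(neg_sorted, candidates, side="left")
    else:
        # positive iff value > c
        tp = n_pos - np.searchsorted(pos_sorted, candidates, side="right")
        fp = n_neg - np.searchsorted(neg_sorted, candidates, side="right")
    sens = tp / n_pos
    spec = 1 - fp / n_neg
    j = sens + spec - 1
    n_pred_pos = tp + fp
    best_j = j.max()
    tied = np.nonzero(j >= best_j - 1e-12)[0]
    winner = tied[np.argmin(n_pred_pos[tied])]
    return DichotomizationRule(
        marker=marker, direction=d, cutoff=float(candidates[winner]),
        youden_j=float(j[winner]), sensitivity=float(sens[winner] * 100),
        specificity=float(spec[winner] * 100),
    )


# -- DeLong machinery --------------------------------------------------------

def _placements(values, labels, direction):
    """AUC plus DeLong structural components (placement values).

    V10[i] = fraction of negatives scored below positive i (ties half);
    V01[j] = fraction of positives scored above negative j (ties half).
    """
    v, y = _split(values, labels)
    s = _as_scores(v, direction)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    r_all = rankdata(s)
    r_pos = rankdata(s[y])
    r_neg = rankdata(s[~y])
    v10 = (r_all[y] - r_pos) / n_neg
    v01 = 1.0 - (r_all[~y] - r_neg) / n_pos
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_ci(values, labels, direction: str = "above",
                  alpha: float = 0.05, scale: str = "wald") -> AUCResult:
    """AUC with DeLong standard error and confidence interval.

    ``scale="wald"`` gives a normal interval on the AUC scale truncated to
    [0, 1]; ``scale="logit"`` transforms through the logit for intervals that
    respect the bounds near 0/1.
    """
    v, y = _split(values, labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least two members")
    auc, v10, v01 = _placements(v, y, direction)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    if scale == "wald":
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    elif scale == "logit":
        if se == 0 or auc in (0.0, 1.0):
            lo = hi = auc
        else:
            lg = np.log(auc / (1 - auc))
            se_lg = se / (auc * (1 - auc))
            lo = 1 / (1 + np.exp(-(lg - z * se_lg)))
            hi = 1 / (1 + np.exp(-(lg + z * se_lg)))
    else:
        raise ValueError(f"unknown CI scale {scale!r}")
    return AUCResult(auc=auc, standard_error=se, ci_low=float(lo),
                     ci_high=float(hi), alpha=alpha)


def delong_paired_test(values_a, values_b, labels,
                       directions=("above", "above")):
    """DeLong test for two correlated AUCs measured on the same records.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value for the
    AUC difference.  Identical markers give z = 0, p = 1.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if va.shape != vb.shape or va.shape != y.shape:
        raise ValueError("both markers must score the same records")
    auc_a, v10_a, v01_a = _placements(va, y, directions[0])
    auc_b, v10_b, v01_b = _placements(vb, y, directions[1])
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        z_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z_stat = diff / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z_stat)))
    return auc_a, auc_b, float(z_stat), p


# -- analytic AUCs and predictive values -------------------------------------

def binormal_auc(mu_pos, sd_pos, mu_neg, sd_neg,
                 direction: str = "above") -> float:
    """Closed-form AUC when both classes are Gaussian:
    Phi(delta / sqrt(sd_pos^2 + sd_neg^2)), oriented per ``direction``."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    delta = mu_pos - mu_neg
    if _check_direction(direction) == "below":
        delta = -delta
    return float(norm.cdf(delta / np.hypot(sd_pos, sd_neg)))


def binary_marker_auc(rate_pos: float, rate_neg: float) -> float:
    """AUC of a Bernoulli marker: (rate_pos + (1 - rate_neg)) / 2."""
    for r in (rate_pos, rate_neg):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    return (rate_pos + (1 - rate_neg)) / 2


def ppv_npv(sens: float, spec: float, prevalence: float):
    """Prevalence-adjusted predictive values via Bayes' rule.

    ``sens``/``spec`` in percent, ``prevalence`` a proportion in (0, 1);
    returns ``(ppv, npv)`` in percent.  Degenerate corners where no record
    tests positive (or negative) have no defined limit and return NaN with a
    warning.
    """
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("sensitivity/specificity must lie in [0, 100]")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    se, sp, p = sens / 100.0, spec / 100.0, prevalence
    denom_pos = se * p + (1 - sp) * (1 - p)
    denom_neg = (1 - se) * p + sp * (1 - p)
    if denom_pos == 0:
        warnings.warn("no record tests positive; PPV undefined", stacklevel=2)
        ppv = np.nan
    else:
        ppv = 100 * se * p / denom_pos
    if denom_neg == 0:
        warnings.warn("no record tests negative; NPV undefined", stacklevel=2)
        npv = np.nan
    else:
        npv = 100 * sp * (1 - p) / denom_neg
    return float(ppv), float(npv)
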