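"""Data-driven CSF amyloid-positivity cutoffs via Gaussian mixtures.

A two-component Gaussian mixture is fitted to the Abeta42/Abeta40 ratio
(separately per assay platform) and the positivity cutoff is taken as the
point between the component means where the weighted component densities
cross — equivalently, where the posterior probability of either component is
0.5. Classification is a strict less-than comparison against the assay's
cutoff: low ratios indicate amyloid pathology.

The EM fitter is one-dimensional and self-contained so the per-iteration
log-likelihood trace (and its guaranteed monotonicity) is part of the
returned fit object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from amypredict import reference

__all__ = [
    "GMMFit", "AssayCutoffs", "fit_gmm", "derive_cutoff",
    "classify_amyloid", "derive_assay_cutoffs",
]


@dataclass
class GMMFit:
    """A fitted k-component univariate Gaussian mixture.

    Components are stored sorted by mean ascending; ``ll_trace`` is the
    per-iteration log-likelihood of the winning restart (monotone
    non-decreasing by the EM guarantee).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return len(self.means)


@dataclass
class AssayCutoffs:
    """Assay-specific positivity cutoffs on the x10 ratio scale.

    Direction is fixed: a ratio strictly below the cutoff is positive.
    """

    innotest_cutoff: float = reference.INNOTEST_CUTOFF
    lumipulse_cutoff: float = reference.LUMIPULSE_CUTOFF

    def __post_init__(self):
        if self.innotest_cutoff <= 0 or self.lumipulse_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    def for_assay(self, assay: str) -> float:
        try:
            return {"Innotest": self.innotest_cutoff,
                    "Lumipulse": self.lumipulse_cutoff}[assay]
        except KeyError:
            raise ValueError(f"unknown assay label: {assay!r}") from None


def _loglik_matrix(x, weights, means, sds):
    # (n, k) log of weighted component densities
    return np.log(weights) + norm.logpdf(x[:, None], means[None, :], sds[None, :])


def _em(x, k, means0, sds0, weights0, tol, max_iter, var_floor):
    weights, means, sds = weights0.copy(), means0.copy(), sds0.copy()
    trace = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lw = _loglik_matrix(x, weights, means, sds)
        ll_rows = logsumexp(lw, axis=1)
        ll = float(ll_rows.sum())
        trace.append(ll)
        if ll - prev < tol and n_iter > 1:
            converged = True
            break
        prev = ll
        # E-step
        resp = np.exp(lw - ll_rows[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / nk.sum()
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
    return weights, means, sds, trace, n_iter, converged


def _quantile_init(x, k):
    blocks = np.array_split(np.sort(x), k)
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(), 1e-3 * (x.std() + 1e-12)) for b in blocks])
    weights = np.array([len(b) for b in blocks], dtype=float)
    return means, sds, weights / weights.sum()


def _kmeans_init(x, k, rng):
    # Lloyd's algorithm in 1-D, centers seeded from random data points
    centers = rng.choice(np.unique(x), size=k, replace=False).astype(float)
    for _ in range(50):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == j].mean() if np.any(assign == j)
                        else centers[j] for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    means, sds, weights = [], [], []
    s_global = x.std() + 1e-12
    for j in range(k):
        xj = x[assign == j]
        means.append(xj.mean() if len(xj) else centers[j])
        sds.append(max(xj.std(), 1e-3 * s_global) if len(xj) > 1 else s_global)
        weights.append(max(len(xj), 1))
    w = np.array(weights, dtype=float)
    return np.array(means), np.array(sds), w / w.sum()


def fit_gmm(values, k: int = 2, init: str = "quantile", tol: float = 1e-8,
            max_iter: int = 500, n_restarts: int = 5, seed: int = 0) -> GMMFit:
    """Fit a k-component Gaussian mixture by EM with restarts.

    The first restart uses the deterministic ``init`` strategy ("quantile"
    blocks of the sorted data, or 1-D k-means); subsequent restarts are
    randomly initialized from the data.  The best restart by final
    log-likelihood wins.  A variance floor of 1e-6 times the sample variance
    guards against component collapse.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if init not in ("quantile", "kmeans"):
        raise ValueError(f"unknown init strategy {init!r}")
    n_distinct = len(np.unique(x))
    if n_distinct < 2 * k:
        if n_distinct == 1:
            raise ValueError(
                "all values identical: a Gaussian mixture is degenerate on "
                "constant data"
            )
        raise ValueError(f"need at least {2 * k} distinct values, got {n_distinct}")
    rng = np.random.default_rng(seed)
    var_floor = 1e-6 * x.var()
    s_global = x.std()

    best = None
    for r in range(max(n_restarts, 1)):
        if r == 0:
            if init == "quantile":
                m0, s0, w0 = _quantile_init(x, k)
            else:
                m0, s0, w0 = _kmeans_init(x, k, rng)
        else:
            m0 = rng.choice(np.unique(x), size=k, replace=False).astype(float)
            s0 = np.full(k, s_global)
            w0 = np.full(k, 1.0 / k)
        w, m, s, trace, n_iter, conv = _em(x, k, m0, s0, w0, tol, max_iter, var_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, m, s, trace, n_iter, conv)

    w, m, s, trace, n_iter, conv = best
    order = np.argsort(m)
    return GMMFit(
        weights=w[order], means=m[order], sds=s[order],
        log_likelihood=float(trace[-1]), n_iter=n_iter, converged=conv,
        ll_trace=np.asarray(trace),
    )


def derive_cutoff(fit: GMMFit, tol: float = 1e-8) -> float:
    """Positivity cutoff = crossing of the two weighted component densities.

    Between the means, w1*N(x|m1,s1) = w2*N(x|m2,s2) is solved by bisection
    to ``tol``.  If no crossing lies between the means (possible with very
    unequal weights and variances), the density crossing nearest the lower
    mean is returned and a warning is issued.
    """
    if fit.k != 2:
        raise ValueError("cutoff derivation requires a two-component fit")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if m1 == m2:
        raise ValueError("component means are identical; no cutoff exists")

    def f(x):
        return (np.log(w1) + norm.logpdf(x, m1, s1)
                - np.log(w2) - norm.logpdf(x, m2, s2))

    if f(m1) > 0 > f(m2):
        lo, hi = m1, m2
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # no sign change between the means: solve the quadratic
    # log-density-difference exactly and take the root nearest the lower mean
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log(w1 / s1) - np.log(w2 / s2))
    if abs(a) < 1e-300:
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("component densities never cross")
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
    cutoff = float(roots[np.argmin(np.abs(roots - m1))])
    warnings.warn(
        "no density crossing between the component means; returning the "
        "crossing nearest the lower mean", stacklevel=2,
    )
    return cutoff


def classify_amyloid(ratio: float, assay: str,
                     cutoffs: AssayCutoffs | None = None) -> bool:
    """Amyloid-positive iff the ratio is strictly below the assay cutoff."""
    if cutoffs is None:
        cutoffs = AssayCutoffs()
    if not ratio > 0:
        raise ValueError("abeta ratio must be positive")
    return ratio < cutoffs.for_assay(assay)


def derive_assay_cutoffs(cohort: pd.DataFrame, value_column: str = "abeta_ratio",
                         assay_column: str = "csf_assay", seed: int = 0,
                         **fit_kwargs) -> tuple[AssayCutoffs, dict[str, GMMFit]]:
    """Fit a two-component mixture per assay and derive both cutoffs."""
    fits: dict[str, GMMFit] = {}
    derived: dict[str, float] = {}
    for assay, grp in cohort.groupby(assay_column):
        vals = grp[value_column].dropna().to_numpy()
        fit = fit_gmm(vals, k=2, seed=seed, **fit_kwargs)
        fits[str(assay)] = fit
        derived[str(assay)] = derive_cutoff(fit)
    try:
        cutoffs = AssayCutoffs(
            innotest_cutoff=derived["Innotest"],
            lumipulse_cutoff=derived["Lumipulse"],
        )
    except KeyError as exc:
        raise ValueError(f"cohort lacks assay {exc} records") from None
    return cutoffs, fits
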