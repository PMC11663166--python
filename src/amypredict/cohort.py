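"""Seeded synthetic memory-clinic cohorts.

The generator emulates the group-level structure of a tertiary memory-clinic
population: fixed numbers of CSF-amyloid-negative and -positive participants,
per-group Gaussian marker distributions (cognition, normalized regional brain
volumes, visual and computed atrophy rating scales), per-group Bernoulli
rates (APOE4 carriage, sex, anticoagulation, MRI availability), a per-assay
two-component mixture for the CSF Abeta42/Abeta40 ratio, and per-variable
missingness that is completely at random.

Markers are drawn conditionally independently given amyloid group — only
group marginals are configured, so no within-group correlation structure is
imposed. Record labels and CSF ratios never contradict: the ratio is
rejection-sampled from the group's own mixture component until it falls on
the correct side of the assay cutoff.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from amypredict import reference

__all__ = [
    "MarkerSpec", "CSFMixture", "CohortConfig", "default_config",
    "generate_cohort", "apply_missingness", "read_cohort", "write_cohort",
    "COLUMN_ORDER",
]

#: Fixed column order of cohort tables (CSV header order).
COLUMN_ORDER = [
    "id", "age", "sex", "education", "diagnosis", "etiology_tag",
    "moca", "mmse", "ravlt_immediate", "apoe4_carrier",
    "csf_assay", "abeta_ratio", "amyloid_positive",
    "hippocampus_ml", "angular_gyrus_ml",
    "visual_mta", "visual_gca", "visual_pa", "visual_fazekas",
    "computed_mta", "computed_gca_frontal", "computed_gca_parietal",
    "computed_gca_occipital", "computed_pa", "computed_fazekas",
    "anticoagulant", "mri_available",
]

BOOL_COLUMNS = ["apoe4_carrier", "amyloid_positive", "anticoagulant", "mri_available"]
STRING_COLUMNS = ["id", "sex", "diagnosis", "etiology_tag", "csf_assay"]


@dataclass
class MarkerSpec:
    """Per-group Gaussian for one continuous marker.

    ``lo``/``hi`` are clipping bounds applied after the draw (``None``
    disables a bound); ``integer`` rounds to the nearest integer after
    clipping (used for test scores and visual rating scales).
    """

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    lo: float | None = None
    hi: float | None = None
    integer: bool = False

    def validate(self) -> None:
        if self.sd_neg <= 0 or self.sd_pos <= 0:
            raise ValueError("marker standard deviations must be positive")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ValueError("clipping bounds require lo < hi")


@dataclass
class CSFMixture:
    """Two-component Gaussian mixture for one assay's Abeta42/Abeta40 ratio.

    Component 0 is the amyloid-positive (low-ratio) component; component 1
    the amyloid-negative one.  ``cutoff`` is the assay positivity cutoff:
    positives are truncated strictly below it, negatives at or above it.
    """

    weight_positive: float
    mean_positive: float
    sd_positive: float
    mean_negative: float
    sd_negative: float
    cutoff: float

    def validate(self) -> None:
        if not 0 < self.weight_positive < 1:
            raise ValueError("mixture weight must lie in (0, 1)")
        if self.sd_positive <= 0 or self.sd_negative <= 0:
            raise ValueError("mixture sds must be positive")
        if self.cutoff <= 0:
            raise ValueError("assay cutoff must be positive")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Group sizes are fixed counts, not draws, so the configured prevalence is
    exact by construction.  ``missing_observed`` holds observed Ns per
    variable *at* ``missing_reference_n`` participants; for other cohort
    sizes the counts are scaled proportionally.
    """

    n_negative: int = 198
    n_positive: int = 92
    markers: dict[str, MarkerSpec] = field(default_factory=dict)
    # binary rates per group: name -> (rate_negative, rate_positive)
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    # diagnosis probabilities per group: (SCI, MCI, dementia)
    diagnosis_probs_negative: tuple[float, float, float] = (0.0, 0.0, 1.0)
    diagnosis_probs_positive: tuple[float, float, float] = (0.0, 0.0, 1.0)
    # etiology mix for negative-group MCI/dementia: label -> probability
    etiology_probs_negative: dict[str, float] = field(default_factory=dict)
    # probability an amyloid-positive MCI/dementia case is an atypical variant
    atypical_ad_rate: float = 0.0
    innotest_fraction: float = 0.5
    csf_mixtures: dict[str, CSFMixture] = field(default_factory=dict)
    missing_observed: dict[str, int] = field(default_factory=dict)
    missing_reference_n: int = 290
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_negative + self.n_positive

    def validate(self) -> None:
        if self.n_negative <= 0 or self.n_positive <= 0:
            raise ValueError("group sizes must be positive")
        for name, spec in self.markers.items():
            try:
                spec.validate()
            except ValueError as exc:
                raise ValueError(f"marker {name!r}: {exc}") from exc
        for name, (rn, rp) in self.rates.items():
            if not (0 <= rn <= 1 and 0 <= rp <= 1):
                raise ValueError(f"rate {name!r} outside [0, 1]")
        for probs in (self.diagnosis_probs_negative, self.diagnosis_probs_positive):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("diagnosis proportions must be a simplex")
        if not 0 <= self.innotest_fraction <= 1:
            raise ValueError("innotest_fraction outside [0, 1]")
        for assay, mix in self.csf_mixtures.items():
            try:
                mix.validate()
            except ValueError as exc:
                raise ValueError(f"assay {assay!r}: {exc}") from exc
        for name, n_obs in self.missing_observed.items():
            if not 0 <= n_obs <= self.missing_reference_n:
                raise ValueError(f"observed count for {name!r} outside cohort")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["markers"] = {k: MarkerSpec(**v) for k, v in d.get("markers", {}).items()}
        d["rates"] = {k: tuple(v) for k, v in d.get("rates", {}).items()}
        d["csf_mixtures"] = {
            k: CSFMixture(**v) for k, v in d.get("csf_mixtures", {}).items()
        }
        for key in ("diagnosis_probs_negative", "diagnosis_probs_positive"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load a config from a JSON or YAML document."""
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            d = yaml.safe_load(text)
        return cls.from_dict(d)


def default_config() -> CohortConfig:
    """Configuration reproducing the development cohort's printed structure.

    Group sizes 198/92; marker means and SDs from the published per-group
    summaries; APOE4 carriage 29.8%/69.6%; diagnosis mix 67.1/19.1/13.6%
    (SCI/MCI/dementia) among negatives vs 22.8/25.0/52.2% among positives;
    per-variable observed Ns as published.  CSF mixtures are parameterized so
    the weighted density crossing sits at the assay cutoffs (0.60 Innotest,
    0.86 Lumipulse on the x10 scale).
    """
    g = reference.GROUP_STATS

    def m(name, lo=None, hi=None, integer=False):
        (mn, sn), (mp, sp) = g[name]
        return MarkerSpec(mn, sn, mp, sp, lo=lo, hi=hi, integer=integer)

    markers = {
        "age": m("age", lo=18.0, hi=100.0),
        "education": m("education", lo=0.0, hi=30.0),
        "moca": m("moca", lo=0.0, hi=30.0, integer=True),
        "mmse": m("mmse", lo=0.0, hi=30.0, integer=True),
        "ravlt_immediate": m("ravlt_immediate", lo=0.0, hi=75.0, integer=True),
        "hippocampus_ml": m("hippocampus_ml", lo=0.5),
        "angular_gyrus_ml": m("angular_gyrus_ml", lo=0.5),
        "visual_mta": m("visual_mta", lo=0.0, hi=4.0, integer=True),
        "visual_gca": m("visual_gca", lo=0.0, hi=3.0, integer=True),
        "visual_pa": m("visual_pa", lo=0.0, hi=3.0, integer=True),
        "visual_fazekas": m("visual_fazekas", lo=0.0, hi=3.0, integer=True),
        "computed_mta": m("computed_mta", lo=0.0, hi=4.0),
        "computed_gca_frontal": m("computed_gca_frontal", lo=0.0, hi=3.0),
        "computed_gca_parietal": m("computed_gca_parietal", lo=0.0, hi=3.0),
        "computed_gca_occipital": m("computed_gca_occipital", lo=0.0, hi=3.0),
        "computed_pa": m("computed_pa", lo=0.0, hi=3.0),
        "computed_fazekas": m("computed_fazekas", lo=0.0, hi=3.0),
    }
    dn = np.array(reference.DIAGNOSIS_COUNTS_NEGATIVE, dtype=float)
    dp = np.array(reference.DIAGNOSIS_COUNTS_POSITIVE, dtype=float)
    w_pos = reference.N_POSITIVE / reference.N_TOTAL
    return CohortConfig(
        n_negative=reference.N_NEGATIVE,
        n_positive=reference.N_POSITIVE,
        markers=markers,
        rates={
            "female": reference.FEMALE_RATES,
            "apoe4_carrier": reference.APOE4_RATES,
            "anticoagulant": (0.10, 0.10),
            "mri_available": (0.95, 0.95),
        },
        diagnosis_probs_negative=tuple(dn / dn.sum()),
        diagnosis_probs_positive=tuple(dp / dp.sum()),
        etiology_probs_negative={
            "unspecified": 0.70, "psychiatric": 0.12, "vascular": 0.05,
            "alcohol-related": 0.04, "FTD": 0.04, "other": 0.05,
        },
        atypical_ad_rate=1.0 / 71.0,
        innotest_fraction=0.5,
        csf_mixtures={
            "Innotest": CSFMixture(w_pos, 0.42, 0.08, 0.95, 0.15,
                                   reference.INNOTEST_CUTOFF),
            "Lumipulse": CSFMixture(w_pos, 0.63, 0.12, 1.30, 0.22,
                                    reference.LUMIPULSE_CUTOFF),
        },
        missing_observed=dict(reference.OBSERVED_COUNTS),
        missing_reference_n=reference.N_TOTAL,
    )


def _draw_marker(rng: np.random.Generator, spec: MarkerSpec,
                 positive: np.ndarray) -> np.ndarray:
    mean = np.where(positive, spec.mean_pos, spec.mean_neg)
    sd = np.where(positive, spec.sd_pos, spec.sd_neg)
    x = rng.normal(mean, sd)
    if spec.lo is not None or spec.hi is not None:
        x = np.clip(x, spec.lo, spec.hi)
    if spec.integer:
        x = np.rint(x)
    return x


def _draw_ratio(rng: np.random.Generator, mix: CSFMixture,
                positive: bool) -> float:
    """Rejection-sample the CSF ratio from the group's component, truncated
    at the assay cutoff so label and ratio never contradict."""
    if positive:
        mean, sd = mix.mean_positive, mix.sd_positive
    else:
        mean, sd = mix.mean_negative, mix.sd_negative
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x <= 0:
            continue
        if positive and x < mix.cutoff:
            return x
        if not positive and x >= mix.cutoff:
            return x
    raise RuntimeError(
        "rejection sampling failed: component mass on the wrong side of the "
        "assay cutoff is too small"
    )


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Exactly ``n_negative + n_positive`` records; ``amyloid_positive`` is the
    group label and is consistent with ``abeta_ratio`` vs the assay cutoff by
    construction.  Identical ``(config, seed)`` yield identical tables.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_total
    positive = np.zeros(n, dtype=bool)
    positive[config.n_negative:] = True
    # shuffle so group blocks are interleaved like a consecutive clinic series
    order = rng.permutation(n)
    positive = positive[order]

    df = pd.DataFrame({"id": [f"P{i + 1:04d}" for i in range(n)]})
    df["amyloid_positive"] = positive

    for name, spec in config.markers.items():
        df[name] = _draw_marker(rng, spec, positive)

    rate_cols = {}
    for name, (rn, rp) in config.rates.items():
        p = np.where(positive, rp, rn)
        rate_cols[name] = rng.random(n) < p
    df["sex"] = np.where(rate_cols.pop("female"), "female", "male")
    for name, vals in rate_cols.items():
        df[name] = vals

    # diagnosis + etiology
    diag_levels = np.array(["SCI", "MCI", "dementia"])
    pn = np.asarray(config.diagnosis_probs_negative)
    pp = np.asarray(config.diagnosis_probs_positive)
    u = rng.random(n)
    cum = np.where(positive[:, None], np.cumsum(pp), np.cumsum(pn))
    diag_idx = (u[:, None] > cum).sum(axis=1).clip(0, 2)
    df["diagnosis"] = diag_levels[diag_idx]

    etiologies = np.full(n, "SCI", dtype=object)
    impaired = diag_idx > 0
    neg_lab = list(config.etiology_probs_negative) or ["unspecified"]
    neg_p = np.array([config.etiology_probs_negative.get(k, 1.0) for k in neg_lab])
    neg_p = neg_p / neg_p.sum()
    for i in np.nonzero(impaired)[0]:
        if positive[i]:
            atyp = rng.random() < config.atypical_ad_rate
            etiologies[i] = "AD-atypical" if atyp else "AD-typical"
        else:
            etiologies[i] = neg_lab[rng.choice(len(neg_lab), p=neg_p)]
    df["etiology_tag"] = etiologies

    # CSF assay + ratio
    assays = list(config.csf_mixtures)
    if len(assays) == 1:
        assay_col = np.full(n, assays[0], dtype=object)
    else:
        innotest = rng.random(n) < config.innotest_fraction
        assay_col = np.where(innotest, "Innotest", "Lumipulse").astype(object)
    df["csf_assay"] = assay_col
    ratios = np.empty(n)
    for i in range(n):
        ratios[i] = _draw_ratio(rng, config.csf_mixtures[assay_col[i]], positive[i])
    df["abeta_ratio"] = ratios

    return df[COLUMN_ORDER].copy()


def apply_missingness(table: pd.DataFrame, config: CohortConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Mask values completely at random, per variable, until the observed N
    matches the configured count (scaled proportionally for non-default
    cohort sizes).  ``id`` and ``amyloid_positive`` are never masked.
    """
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    n = len(table)
    out = table.copy()
    for name, n_obs_ref in config.missing_observed.items():
        if name in ("id", "amyloid_positive"):
            raise ValueError(f"{name!r} can never be masked")
        n_obs = int(round(n_obs_ref * n / config.missing_reference_n))
        if n_obs > n:
            raise ValueError(
                f"requested observed N {n_obs} for {name!r} exceeds cohort size {n}"
            )
        n_missing = n - n_obs
        if n_missing == 0:
            continue
        idx = rng.choice(n, size=n_missing, replace=False)
        if name in BOOL_COLUMNS or name in STRING_COLUMNS:
            out[name] = out[name].astype(object)
        col = out[name].copy()
        col.iloc[idx] = np.nan
        out[name] = col
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV: fixed column order, missing cells empty."""
    table[COLUMN_ORDER].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV back with the dtypes the generator produces.

    Boolean columns become object arrays of True/False with NaN for missing
    (a masked boolean cannot stay a numpy bool).
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMN_ORDER if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks expected columns: {missing}")
    for col in BOOL_COLUMNS:
        if df[col].dtype != bool:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            )
    return df[COLUMN_ORDER]
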