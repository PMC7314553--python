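"""Group-level inference on depth profiles and event-related time courses.

Covers the study's inferential layer: condition contrasts over depth
(mean ± SEM across subjects), response-onset detection by Bonferroni-
corrected one-sample t-tests, classification of depth-profile peaks as
superficial (upper third of the grey matter), Pearson chi-squared comparison
of superficial-peak ratios between areas, and likelihood-ratio tests between
nested linear mixed models (fixed effects for ROI, condition and depth with
chosen two-way interactions; random intercept and depth slope per subject;
fitted by maximum likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SUPERFICIAL_DEPTH_MAX = 1.0 / 3.0  # upper third of grey matter, from the pial/CSF border


# ---------------------------------------------------------------------------
# Condition contrasts
# ---------------------------------------------------------------------------

def condition_contrast(profiles: pd.DataFrame, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Per-subject, per-depth PSC difference ``cond_a − cond_b``, with the
    group mean and SEM across subjects.

    ``profiles`` is long format with columns subject, condition,
    depth_fraction, psc (an ``area`` column, if present, must already be
    filtered to one area).  Raises if any subject misses a condition.
    """
    for c in (cond_a, cond_b):
        if c not in set(profiles["condition"]):
            raise ValueError(f"condition {c!r} not present")
    wide = profiles.pivot_table(
        index=["subject", "depth_fraction"], columns="condition", values="psc"
    )
    if wide[[cond_a, cond_b]].isna().any().any():
        raise ValueError("unbalanced design: some subjects miss a condition/depth cell")
    diff = (wide[cond_a] - wide[cond_b]).rename("delta_psc").reset_index()
    group = diff.groupby("depth_fraction")["delta_psc"].agg(["mean", "std", "count"])
    group["sem"] = group["std"] / np.sqrt(group["count"])
    out = group.reset_index().rename(columns={"count": "n_subjects"})
    out.attrs["per_subject"] = diff
    return out


# ---------------------------------------------------------------------------
# Response-onset detection
# ---------------------------------------------------------------------------

def detect_response_onset(
    group_timecourses: np.ndarray,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> int | None:
    """Earliest time point at which the group signal differs from zero.

    ``group_timecourses`` is (n_subjects × n_timepoints).  Each time point is
    tested with a two-sided one-sample t-test across subjects against 0 at
    the Bonferroni-adjusted level ``alpha / n_tests`` (``n_tests`` defaults
    to the number of in-window time points).  Zero-variance time points are
    skipped with a warning.  Returns the earliest significant index or None.
    """
    y = np.asarray(group_timecourses, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need at least 2 subjects (rows)")
    if n_tests is None:
        n_tests = y.shape[1]
    threshold = alpha / n_tests
    for t in range(y.shape[1]):
        col = y[:, t]
        if np.ptp(col) == 0:
            if col[0] != 0:
                return t  # exactly constant non-zero: trivially different from 0
            warnings.warn(f"zero variance at time point {t}; skipped", stacklevel=2)
            continue
        p = sps.ttest_1samp(col, 0.0).pvalue
        if p < threshold:
            return t
    return None


# ---------------------------------------------------------------------------
# Depth-profile peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakCall:
    """Location of a depth profile's global maximum."""

    peak_depth_fraction: float
    superficial: bool  # within the upper third from the pial surface
    degenerate: bool = False  # all-equal profile; tie rule applied


def classify_peak(
    profile: np.ndarray,
    depth_fractions: np.ndarray,
    tie_rule: str = "superficial",
) -> PeakCall:
    """Global maximum of a depth profile; superficial iff the peak lies
    within the upper third of the grey matter (depth ≤ 1/3 from the pial
    surface).  Exact ties resolve towards the more superficial depth (or the
    deeper one with ``tie_rule='deep'``)."""
    v = np.asarray(profile, dtype=float)
    d = np.asarray(depth_fractions, dtype=float)
    if v.size == 0 or v.size != d.size:
        raise ValueError("profile and depth fractions must be non-empty and matching")
    best = v.max()
    tied = np.flatnonzero(v >= best - 1e-12)
    depths = d[tied]
    depth = depths.min() if tie_rule == "superficial" else depths.max()
    return PeakCall(
        peak_depth_fraction=float(depth),
        superficial=bool(depth <= SUPERFICIAL_DEPTH_MAX + 1e-12),
        degenerate=bool(len(tied) == v.size),
    )


def superficial_ratio_chisq(peak_calls_by_area: dict) -> tuple[float, int, float]:
    """Pearson chi-squared on the areas × {superficial, not} table.

    ``peak_calls_by_area`` maps an area label to either a list of PeakCall
    or a (n_superficial, n_not_superficial) pair.  No continuity correction.
    Pooled comparisons (e.g. V1 vs V2+V3) are expressed by passing summed
    count pairs.  Raises if any expected cell count is 0.
    """
    if len(peak_calls_by_area) < 2:
        raise ValueError("need at least 2 groups")
    table = []
    for area, calls in peak_calls_by_area.items():
        if isinstance(calls, (tuple, list)) and len(calls) == 2 and np.isscalar(calls[0]):
            table.append([float(calls[0]), float(calls[1])])
        else:
            sup = sum(1 for c in calls if c.superficial)
            table.append([float(sup), float(len(calls) - sup)])
    obs = np.asarray(table)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if obs.sum() == 0:
        raise ValueError("expected cell count of 0; table is degenerate")
    expected = row @ col / obs.sum()
    if np.any(expected == 0):
        raise ValueError("expected cell count of 0; table is degenerate")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# Mixed-model likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    """Likelihood-ratio test between nested linear mixed models."""

    statistic: float
    df: int
    p_value: float
    full_formula: str
    null_formula: str
    full_loglik: float
    null_loglik: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("LRT statistic must be non-negative")
        if self.df < 0:
            raise ValueError("df must be non-negative")


def _fit_mixed(formula: str, data: pd.DataFrame, group: str, re_formula: str, methods):
    import statsmodels.formula.api as smf

    last_exc = None
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data[group], re_formula=re_formula)
                fit = model.fit(reml=False, method=method, maxiter=200)
            if np.isfinite(fit.llf):
                return fit
        except Exception as exc:  # try the next optimizer
            last_exc = exc
    raise RuntimeError(f"mixed model failed to converge: {formula!r} ({last_exc})")


def lme_interaction_lrt(
    profiles: pd.DataFrame,
    full_terms: list[str],
    null_terms: list[str],
    response: str = "psc",
    group: str = "subject",
    re_formula: str = "~depth_fraction",
) -> LRTResult:
    """Likelihood-ratio test between nested fixed-effect specifications of a
    linear mixed model.

    Both models share the random structure (intercept + depth slope per
    subject) and are fitted by maximum likelihood, so the statistic
    2·Δloglik is chi-squared with df equal to the fixed-parameter difference.
    ``full_terms`` / ``null_terms`` are patsy terms, e.g.
    ``["roi", "condition", "depth_fraction", "roi:condition"]``; the null
    terms must be a subset of the full terms.
    """
    if not set(null_terms) <= set(full_terms):
        raise ValueError("null model terms must be nested within the full model terms")
    full_formula = f"{response} ~ " + " + ".join(full_terms)
    null_formula = f"{response} ~ " + (" + ".join(null_terms) if null_terms else "1")

    methods = ("lbfgs", "powell", "cg")
    full_fit = _fit_mixed(full_formula, profiles, group, re_formula, methods)
    if set(null_terms) == set(full_terms):
        return LRTResult(0.0, 0, 1.0, full_formula, null_formula, full_fit.llf, full_fit.llf)
    null_fit = _fit_mixed(null_formula, profiles, group, re_formula, methods)

    stat = 2.0 * (full_fit.llf - null_fit.llf)
    df = int(full_fit.df_modelwc - null_fit.df_modelwc)
    if df <= 0:
        raise ValueError("models are not strictly nested (no fixed-parameter difference)")
    if stat < 0:
        # ML surface explored insufficiently; refit with the alternative optimizers
        full_fit = _fit_mixed(full_formula, profiles, group, re_formula, ("powell", "cg", "nm"))
        stat = 2.0 * (full_fit.llf - null_fit.llf)
        stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df))
    return LRTResult(float(stat), df, p, full_formula, null_formula, float(full_fit.llf), float(null_fit.llf))
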