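"""Inferential statistics on bout and transient metrics.

Covers the comparisons the pipeline reports: Pearson correlation (with
t-distribution p and an OLS slope ± 95% CI) between post-onset AUC and bout
duration; Welch and paired t tests; an exact two-sided binomial test of the
proportion of bouts with positive AUC against 0.5; the two-stage step-up
false-discovery-rate procedure of Benjamini, Krieger & Yekutieli; and
day-1-normalized transient frequencies for multi-day designs.

Standard tests are delegated to scipy.stats; the two-stage FDR procedure is
implemented here (first stage: step-up at q' = q/(1+q); the number of
non-rejections estimates the null count m0; second stage: step-up at
q'·m/m0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, DomainError

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "correlate_auc_duration",
    "welch_t",
    "paired_t",
    "positive_auc_proportion",
    "bky_two_stage_fdr",
    "normalize_frequency_by_day",
]


@dataclass
class CorrelationResult:
    """Pearson r with p, plus the OLS slope of y on x and its 95% CI."""

    r: float
    n: int
    p: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    significant: bool


@dataclass
class GroupComparison:
    statistic: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test: str


def correlate_auc_duration(
    durations: np.ndarray, aucs: np.ndarray
) -> CorrelationResult:
    """Pearson correlation of AUC on bout duration, with OLS slope + CI.

    p comes from ``t = r·sqrt((n-2)/(1-r²))`` on n−2 df (two-sided); the
    slope CI is the t-based 95% interval from the regression of AUC on
    duration.
    """
    x = np.asarray(durations, dtype=float)
    y = np.asarray(aucs, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need n >= 3 pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in duration or AUC")
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return CorrelationResult(
        r=float(res.rvalue),
        n=n,
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        significant=bool(res.pvalue < 0.05),
    )


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> GroupComparison:
    """Welch two-sample t test (unequal variances, Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs n >= 2")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=_sem(a),
        sem_b=_sem(b),
        test="welch_t",
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> GroupComparison:
    """Two-sided paired t test (one-sample t on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise DegenerateInputError("need n >= 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise DegenerateInputError("all paired differences are equal")
    res = sps.ttest_rel(x, y)
    return GroupComparison(
        statistic=float(res.statistic),
        df=float(x.size - 1),
        p=float(res.pvalue),
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        sem_a=_sem(x),
        sem_b=_sem(y),
        test="paired_t",
    )


def positive_auc_proportion(aucs: np.ndarray) -> dict:
    """Exact two-sided binomial test of P(AUC > 0) against 0.5.

    Uses the minimum-likelihood two-sided definition: the p value sums the
    probabilities of all outcomes no more likely than the observed count.
    """
    a = np.asarray(aucs, dtype=float)
    a = a[np.isfinite(a)]
    n = a.size
    if n < 1:
        raise DegenerateInputError("need at least one bout")
    k = int((a > 0).sum())
    res = sps.binomtest(k, n, 0.5, alternative="two-sided")
    return {
        "n_positive": k,
        "n": n,
        "proportion": k / n,
        "p": float(res.pvalue),
        "test": "exact_binomial_vs_0.5",
    }


def _bh_stepup(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level q."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    flags = np.zeros(m, dtype=bool)
    if passed.size:
        flags[order[: passed[-1] + 1]] = True
    return flags


def bky_two_stage_fdr(pvals, q: float = 0.01) -> dict:
    """Two-stage step-up FDR procedure (Benjamini–Krieger–Yekutieli).

    Stage 1 runs BH step-up at ``q' = q/(1+q)``; the count of
    non-rejections estimates the number of true nulls ``m0``. If stage 1
    rejects nothing, nothing is rejected; if it rejects everything,
    everything is. Otherwise stage 2 reruns BH at ``q'·m/m0``.

    Returns rejection flags and the per-comparison threshold actually used.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise DomainError("p values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_stepup(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return {"reject": np.zeros(m, dtype=bool), "q_stage2": q1, "r1": 0}
    if r1 == m:
        return {"reject": np.ones(m, dtype=bool), "q_stage2": q1, "r1": m}
    m0 = m - r1
    q2 = q1 * m / m0
    return {"reject": _bh_stepup(p, q2), "q_stage2": q2, "r1": r1}


def normalize_frequency_by_day(freqs: pd.DataFrame) -> pd.DataFrame:
    """Express per-subject transient frequencies as percent of day 1.

    ``freqs`` is long-format with columns ``subject, day, frequency_hz``;
    day 1 is each subject's first listed day. Subjects with a zero (or
    missing) day-1 frequency are excluded with a warning column rather
    than propagating infinities.
    """
    required = {"subject", "day", "frequency_hz"}
    if not required.issubset(freqs.columns):
        raise ValueError(f"freqs must have columns {sorted(required)}")
    out = []
    for subj, grp in freqs.groupby("subject", sort=False):
        grp = grp.sort_values("day")
        base = grp["frequency_hz"].iloc[0]
        if not np.isfinite(base) or base <= 0:
            continue
        g = grp.copy()
        g["percent_of_day1"] = 100.0 * g["frequency_hz"] / base
        out.append(g)
    if not out:
        return pd.DataFrame(
            columns=list(freqs.columns) + ["percent_of_day1"]
        )
    return pd.concat(out, ignore_index=True)
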