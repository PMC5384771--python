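"""Inferential layer: zero-class Poisson estimation and hypothesis tests.

The break-number estimator inverts the Poisson zero class: if effective
breaks per nucleus are Poisson(λ), the fraction of nuclei with no
enriched SC estimates e^(−λ), so λ̂ = −ln(p̂0). Confidence intervals come
from a Wilson interval on p0, log-transformed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BreakEstimate",
    "TestResult",
    "TrendFit",
    "break_rate_from_zero_class",
    "heterosynapsis_attenuation",
    "proportion_z_test",
    "rank_sum_test",
    "contingency_tests",
    "position_trend",
    "percent_decline",
]


@dataclasses.dataclass
class BreakEstimate:
    """Zero-class Poisson estimate of mean effective breaks per nucleus."""

    p0_hat: float
    lambda_hat: float
    ci_low: float
    ci_high: float
    n: int
    censored: bool = False  # p0_hat was 0; lambda is a flagged lower bound


@dataclasses.dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    sidedness: str
    n: Tuple[int, ...]
    note: str = ""


@dataclasses.dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def break_rate_from_zero_class(counts: Sequence[int]) -> BreakEstimate:
    """Estimate λ from the zero class of per-nucleus enriched-SC counts.

    95% CI: Wilson interval on p0, transformed through λ = −ln(p0). When
    no nucleus has zero count, p0 is censored at 1/(2n) and the estimate
    flagged as a lower bound.
    """
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    if n == 0:
        raise ValueError("empty counts")
    k0 = int(np.sum(counts == 0))
    censored = k0 == 0
    p0 = (1.0 / (2 * n)) if censored else k0 / n
    lam = -np.log(p0)
    lo, hi = proportion_confint(max(k0, 1) if censored else k0, n, method="wilson")
    # p0 high -> lambda low
    ci_low = -np.log(min(hi, 1.0)) if hi > 0 else 0.0
    ci_high = -np.log(max(lo, 1.0 / (2 * n)))
    ci_low = max(0.0, ci_low)
    lam = max(0.0, lam)
    return BreakEstimate(
        p0_hat=p0, lambda_hat=float(lam),
        ci_low=float(min(ci_low, lam)), ci_high=float(max(ci_high, lam)),
        n=n, censored=censored,
    )


def heterosynapsis_attenuation(
    est_plain: BreakEstimate, est_translocation: BreakEstimate
) -> float:
    """Percent reduction of inferred effective breaks in the translocation
    cohort relative to the plain cohort: 100·(1 − λ_t/λ_p)."""
    if est_plain.lambda_hat == 0:
        raise ValueError("plain-cohort lambda is 0; attenuation undefined")
    return 100.0 * (1.0 - est_translocation.lambda_hat / est_plain.lambda_hat)


def proportion_z_test(
    k: int, n: int, p0: float, side: str = "one_sided_greater"
) -> TestResult:
    """One-sample proportion z-test without continuity correction.

    z = (k − n·p0) / sqrt(n·p0·(1 − p0)); p from the normal upper tail
    (one_sided_greater) or doubled (two_sided).
    """
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    z = (k - n * p0) / np.sqrt(n * p0 * (1 - p0))
    if side == "one_sided_greater":
        p = float(sps.norm.sf(z))
    elif side == "two_sided":
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown sidedness '{side}'")
    return TestResult(
        method="proportion_z", statistic=float(z), p_value=p, sidedness=side, n=(n,)
    )


def rank_sum_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    side: str = "two_sided",
) -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration for small tie-free samples (≤ 8 per group),
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    alternative = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[
        side
    ]
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            method="mann_whitney", statistic=float(len(a) * len(b) / 2),
            p_value=1.0, sidedness=side, n=(len(a), len(b)),
            note="all values identical",
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(
        method=f"mann_whitney_{method}", statistic=float(res.statistic),
        p_value=float(res.pvalue), sidedness=side, n=(len(a), len(b)),
    )


def contingency_tests(table: Sequence[Sequence[int]], method: str = "fisher") -> TestResult:
    """Fisher exact (2×2, two-sided by the point-probability rule) or
    Pearson chi-square (r×c, no continuity correction)."""
    t = np.asarray(table, dtype=int)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return TestResult(
            method=method, statistic=np.nan, p_value=1.0, sidedness="two_sided",
            n=tuple(t.sum(axis=1)), note="zero margin",
        )
    if method == "fisher":
        if t.shape != (2, 2):
            raise ValueError("Fisher exact requires a 2x2 table")
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(
            method="fisher_exact", statistic=float(odds), p_value=float(p),
            sidedness="two_sided", n=tuple(t.sum(axis=1)),
        )
    if method == "chi2":
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return TestResult(
            method="chi_square", statistic=float(chi2), p_value=float(p),
            sidedness="two_sided", n=tuple(t.sum(axis=1)),
        )
    raise ValueError(f"unknown method '{method}'")


def position_trend(
    plateaus: Sequence[float], positions: Sequence[float]
) -> TrendFit:
    """OLS of recovery plateau against normalized gonad position."""
    y = np.asarray(plateaus, dtype=float)
    x = np.asarray(positions, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("constant positions; trend undefined")
    res = sps.linregress(x, y)
    return TrendFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue), n=len(x),
    )


def percent_decline(median_early: float, median_late: float) -> float:
    """Percent decline of the late median relative to the early median."""
    if median_early <= 0:
        raise ValueError("early median must be positive")
    return 100.0 * (1.0 - median_late / median_early)
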