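"""Descriptive statistics, normality diagnostics, two-group tests, and the
confidence-interval-width sample-size calculator.

All durations are in fractional minutes.  Skewness and kurtosis use the
adjusted (bias-corrected) sample estimators, with exact small-sample
standard errors:

    SE_skew = sqrt( 6 n (n-1) / ((n-2)(n+1)(n+3)) )
    SE_kurt = 2 SE_skew sqrt( (n^2-1) / ((n-3)(n+5)) )

The sample-size rule estimates the total number of observations needed so
that a mean is estimated within a confidence interval of total width D:

    N = 4 sigma^2 (z_crit + z_pwr)^2 / D^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "SampleSizeSpec",
    "TestResult",
    "summarize",
    "se_skewness",
    "se_kurtosis",
    "z_quantile",
    "required_sample_size",
    "welch_t_test",
    "mann_whitney_u",
    "ks_test",
]


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary of a duration vector (minutes)."""

    n: int
    mean: float
    sd: float
    median: float
    skewness: float
    skewness_se: float
    kurtosis_excess: float
    kurtosis_se: float
    degenerate: bool = False


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs and result of the CI-width sample-size calculation."""

    sigma: float
    power: float
    alpha: float
    width: float
    z_crit: float
    z_pwr: float
    n_raw: float
    n_required: int


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group or goodness-of-fit test."""

    name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int = 0
    details: Mapping[str, float] = field(default_factory=dict)


def se_skewness(n: int) -> float:
    """Exact small-sample standard error of the adjusted sample skewness."""
    if n < 4:
        raise ValueError("skewness standard error requires n >= 4")
    n = float(n)
    return math.sqrt(6.0 * n * (n - 1.0) / ((n - 2.0) * (n + 1.0) * (n + 3.0)))


def se_kurtosis(n: int) -> float:
    """Exact small-sample standard error of the excess-kurtosis estimate."""
    if n < 4:
        raise ValueError("kurtosis standard error requires n >= 4")
    nf = float(n)
    return 2.0 * se_skewness(n) * math.sqrt((nf * nf - 1.0) / ((nf - 3.0) * (nf + 5.0)))


def summarize(values) -> SummaryStats:
    """Mean, SD (n-1), median, adjusted skewness / excess kurtosis with SEs.

    Zero-variance samples are flagged ``degenerate`` and report NaN shape
    statistics; standard errors are NaN below n = 4.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("summarize requires at least one value")
    n = int(x.size)
    mean = float(x.mean())
    median = float(np.median(x))
    sd = float(x.std(ddof=1)) if n >= 2 else 0.0
    degenerate = n >= 2 and sd == 0.0

    nan = float("nan")
    if degenerate or n < 3:
        skew = nan
        kurt = nan
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False)) if n >= 4 else nan
    if n >= 4 and not degenerate:
        skew_se = se_skewness(n)
        kurt_se = se_kurtosis(n)
    else:
        skew_se = nan
        kurt_se = nan
    return SummaryStats(
        n=n,
        mean=mean,
        sd=sd,
        median=median,
        skewness=skew,
        skewness_se=skew_se,
        kurtosis_excess=kurt,
        kurtosis_se=kurt_se,
        degenerate=degenerate,
    )


def z_quantile(p: float) -> float:
    """Inverse standard-normal CDF (standard normal deviate) at ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie strictly between 0 and 1")
    return float(sps.norm.ppf(p))


def required_sample_size(
    sigma: float, power: float, alpha: float, width: float
) -> SampleSizeSpec:
    """Total N to estimate a mean within a CI of total width ``width``.

    ``N = 4 sigma^2 (z_crit + z_pwr)^2 / width^2`` with
    ``z_crit = z_quantile(1 - alpha/2)`` and ``z_pwr = z_quantile(power)``.
    The integer requirement is the floor of the raw value; the raw value is
    reported alongside.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if width <= 0:
        raise ValueError("CI width must be positive")
    z_crit = z_quantile(1.0 - alpha / 2.0)
    z_pwr = z_quantile(power)
    n_raw = 4.0 * sigma**2 * (z_crit + z_pwr) ** 2 / width**2
    return SampleSizeSpec(
        sigma=sigma,
        power=power,
        alpha=alpha,
        width=width,
        z_crit=z_crit,
        z_pwr=z_pwr,
        n_raw=n_raw,
        n_required=int(math.floor(n_raw)),
    )


def welch_t_test(a, b) -> TestResult:
    """Two-tailed Welch (unequal-variance) t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise ValueError("degenerate groups: both have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        details={"mean_a": float(a.mean()), "mean_b": float(b.mean())},
    )


def _mwu_enumerate_midranks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Handles ties via midranks.  Two-sided p = min(1, 2 min(P(U<=u), P(U>=u)))
    over the permutation-null distribution of U for the first group.
    """
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = a.size
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    n = pooled.size
    total = math.comb(n, na)
    le = 0
    ge = 0
    base = na * (na + 1) / 2.0
    for idx in combinations(range(n), na):
        u = float(ranks[list(idx)].sum() - base)
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def mann_whitney_u(a, b, exact_limit: int = 20, max_enumeration: int = 200_000) -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for the first group).

    Exact when both groups have at most ``exact_limit`` observations
    (enumeration when ties are present, provided the number of group
    assignments stays below ``max_enumeration``); otherwise the midrank
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= exact_limit and b.size <= exact_limit
    ranks = sps.rankdata(pooled)
    rank_sum_a = float(ranks[: a.size].sum())
    rank_sum_b = float(ranks[a.size :].sum())
    if small and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        stat, p, method = float(res.statistic), float(res.pvalue), "exact"
    elif small and math.comb(a.size + b.size, a.size) <= max_enumeration:
        stat, p = _mwu_enumerate_midranks(a, b)
        method = "exact-enumeration"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        stat, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
    return TestResult(
        name=f"mann_whitney_u[{method}]",
        statistic=stat,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        details={"rank_sum_a": rank_sum_a, "rank_sum_b": rank_sum_b},
    )


def ks_test(x, mu: float, sigma: float, min_n: int = 10) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against Normal(mu, sigma)."""
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        raise ValueError(f"KS test requires at least {min_n} observations")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    res = sps.kstest(x, "norm", args=(mu, sigma), method="asymp")
    return TestResult(
        name="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(x.size),
        details={"mu": float(mu), "sigma": float(sigma)},
    )
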