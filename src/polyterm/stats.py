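"""Statistical tests reported by the pipeline.

Each test is implemented directly from its definition so it can be verified
against closed forms or exhaustive enumeration: Fisher's exact test sums
hypergeometric probabilities over the full support, the chi-squared test is
the Pearson statistic on a 2xK table, the two-sample Kolmogorov-Smirnov
test takes the supremum ECDF gap with the asymptotic Kolmogorov P value,
and the t test is Welch's with Satterthwaite degrees of freedom. scipy is
used only for distribution primitives (log-gamma, survival functions).
"""
from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import special


class StatsError(ValueError):
    pass


class ChiSquaredResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float
    small_expected: bool  # any expected count < 5
    dropped_columns: int  # zero-margin columns removed


class KsResult(NamedTuple):
    statistic: float
    pvalue: float


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float
    zero_variance: bool


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise StatsError("negative count in contingency table")
    if not np.all(arr == np.floor(arr)):
        raise StatsError("non-integer count in contingency table")
    return arr.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact P for a 2x2 table.

    Uses the minimum-likelihood rule: the P value is the sum of
    hypergeometric probabilities, over all tables with the observed margins,
    that do not exceed the probability of the observed table (with a tiny
    relative slack to absorb floating-point ties).
    """
    arr = _as_2x2(table)
    a, b = arr[0]
    c, d = arr[1]
    n = a + b + c + d
    if n == 0:
        raise StatsError("empty contingency table")
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # margins admit a single table
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        _lbinom(r1, k)
        + _lbinom(r2, c1 - k)
        - _lbinom(n, c1)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[a - kmin]
    p = pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()
    return float(min(p, 1.0))


def _lbinom(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def chi_squared(table) -> ChiSquaredResult:
    """Pearson chi-squared test on a 2xK contingency table.

    Columns with a zero margin are dropped with the degrees of freedom
    reduced accordingly; no continuity correction is applied.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise StatsError(f"expected a 2xK table with K >= 2, got {arr.shape}")
    if np.any(arr < 0):
        raise StatsError("negative count in contingency table")
    col_sums = arr.sum(axis=0)
    keep = col_sums > 0
    dropped = int((~keep).sum())
    arr = arr[:, keep]
    if arr.shape[1] < 2:
        raise StatsError("fewer than two nonzero columns")
    row_sums = arr.sum(axis=1)
    if np.any(row_sums == 0):
        raise StatsError("zero row margin")
    total = arr.sum()
    expected = np.outer(row_sums, arr.sum(axis=0)) / total
    stat = float(((arr - expected) ** 2 / expected).sum())
    df = arr.shape[1] - 1
    pvalue = float(special.chdtrc(df, stat))
    return ChiSquaredResult(stat, df, pvalue, bool((expected < 5).any()), dropped)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum absolute gap between the two ECDFs; the P value uses
    the asymptotic Kolmogorov distribution at effective sample size
    n_x * n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 2 or y.size < 2:
        raise StatsError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    en = x.size * y.size / (x.size + y.size)
    pvalue = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return KsResult(d, pvalue)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("both samples need at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        # degenerate: no within-group variance
        if diff == 0.0:
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, True)
        return WelchResult(math.copysign(math.inf, diff),
                           float(a.size + b.size - 2), 0.0, True)
    sa, sb = va / a.size, vb / b.size
    t = diff / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1)
    )
    pvalue = float(2.0 * special.stdtr(df, -abs(t)))
    return WelchResult(float(t), float(df), pvalue, False)


def proportion_sd(p: float, n: int) -> float:
    """Binomial standard deviation of a proportion: sqrt(p(1-p)/N)."""
    if not 0.0 <= p <= 1.0:
        raise StatsError(f"proportion {p} outside [0, 1]")
    if n < 1:
        raise StatsError("N must be >= 1")
    return math.sqrt(p * (1.0 - p) / n)
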