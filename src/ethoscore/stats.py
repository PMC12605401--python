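"""Closed-form small-sample statistics for DI and density data.

One-sample t against zero, Pearson correlation with the simple
least-squares fit, and the r <-> R-squared consistency check used in
report tables.  Two-sided p-values throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["OneSampleTResult", "RegressionResult", "one_sample_t",
           "pearson_and_fit", "r2_consistency"]


@dataclass(frozen=True)
class OneSampleTResult:
    t: float
    df: int
    p_two_sided: float
    n: int
    mean: float
    mu0: float


@dataclass(frozen=True)
class RegressionResult:
    r: float
    r_squared: float
    slope: float
    intercept: float
    p: float
    n: int


def one_sample_t(values, mu0: float = 0.0) -> OneSampleTResult:
    """t = (mean - mu0) / (sd / sqrt(n)), sd with the n-1 denominator;
    two-sided p from Student's t with df = n - 1."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t requires n >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("one-sample t undefined for zero sample variance")
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return OneSampleTResult(t=t, df=df, p_two_sided=float(p), n=n,
                            mean=mean, mu0=mu0)


def pearson_and_fit(x, y) -> RegressionResult:
    """Product-moment r plus the least-squares line; p from
    t = r * sqrt((n - 2) / (1 - r^2)) with df = n - 2 (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(np.dot(xm, xm))
    syy = float(np.dot(ym, ym))
    sxy = float(np.dot(xm, ym))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for zero variance")
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return RegressionResult(r=r, r_squared=r * r, slope=slope,
                            intercept=intercept, p=p, n=n)


def r2_consistency(r: float) -> float:
    """Square a correlation coefficient, rounded to 3 decimals for
    comparison against reported coefficients of determination."""
    if abs(r) > 1.0:
        raise ValueError(f"correlation coefficient out of range: {r}")
    return round(r * r, 3)
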