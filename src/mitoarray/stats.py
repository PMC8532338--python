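"""Statistical comparisons used by the benchmark.

Fisher's exact test is the two-sided point-probability version (the
convention of mainstream statistical software): the p-value sums the
hypergeometric probabilities of every table with the observed margins whose
point probability does not exceed that of the observed table, with a small
relative tolerance for floating-point ties.  Correlations are sample
Pearson r with the two-sided t transform on n-2 degrees of freedom, and two
correlations from independent groups are compared with Fisher's (1925)
z-transform test.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "CorrelationResult",
    "fisher1925_z",
    "fishers_exact_2x2",
    "mean_sd_difference",
    "pearson_r",
    "steiger_z_dependent",
]

_REL_TOL = 1e-7


class ContingencyTable2x2(NamedTuple):
    """Counts (a, b) over (c, d): rows = groups, columns = outcome."""

    a: int
    b: int
    c: int
    d: int


class CorrelationResult(NamedTuple):
    r: float
    n: int
    p: float


def fishers_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds ratio, p).

    The odds ratio is the sample ratio ad/bc (inf when bc = 0 and ad > 0,
    NaN for 0/0).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1 = a + b
    col1 = a + c
    # hypergeometric support for the top-left cell
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return odds, p


def pearson_r(x, y) -> CorrelationResult:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, p=float(res.pvalue))


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given r via the t transform with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return 2.0 * float(sps.t.sf(abs(t), n - 2))


def fisher1925_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two correlations from independent groups (Fisher 1925).

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    standard-normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both groups")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, p


def steiger_z_dependent(
    r1: float, r2: float, r12: float, n: int
) -> tuple[float, float]:
    """Compare two overlapping dependent correlations sharing one variable
    (Steiger 1980 / Meng–Rosenthal–Rubin).

    ``r12`` is the correlation between the two non-shared variables.
    Provided for completeness next to the independent-groups test.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    rbar2 = (r1 * r1 + r2 * r2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (math.atanh(r1) - math.atanh(r2)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r12) * h)
    )
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, p


def mean_sd_difference(series_a, series_b) -> tuple[float, float]:
    """Mean and sample SD of the paired differences a_i - b_i."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    return float(diff.mean()), float(diff.std(ddof=1))
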