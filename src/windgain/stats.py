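"""Small result containers around the classical tests used throughout.

Everything here is a thin, explicitly-typed wrapper over :mod:`scipy.stats`
with two additions the pipeline needs: degenerate inputs (zero variance) are
flagged instead of producing silent NaNs, and degrees of freedom are always
reported alongside the statistic so downstream reports can print
``t_df = ...`` style lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTResult",
    "TwoSampleTResult",
    "CorrelationResult",
    "paired_t",
    "two_sample_t",
    "pearson",
]


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test on matched observations."""

    statistic: float
    df: int
    pvalue: float
    n: int
    mean_diff: float
    #: True when all pairwise differences are identical (zero variance);
    #: the p-value is then reported at the machine floor (0.0).
    degenerate: bool = False


@dataclass(frozen=True)
class TwoSampleTResult:
    statistic: float
    df: float
    pvalue: float
    n1: int
    n2: int
    equal_var: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    pvalue: float
    n: int
    #: True when either variable has zero variance (r undefined).
    degenerate: bool = False


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test of ``y`` against ``x``.

    The statistic is ``mean(d) / (sd(d)/sqrt(n))`` with ``d = y - x`` and
    ``df = n - 1``. If all differences are equal (sd == 0) the result is
    flagged degenerate with ``p = 0.0`` (any nonzero mean difference is then
    infinitely many standard errors from zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t expects two 1-d arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = y - x
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        stat = np.inf if mean > 0 else (-np.inf if mean < 0 else np.nan)
        return PairedTResult(stat, n - 1, 0.0 if mean != 0 else 1.0, n, mean, True)
    stat = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(stat), n - 1)
    return PairedTResult(float(stat), n - 1, float(p), n, mean, False)


def two_sample_t(a, b, equal_var: bool = True) -> TwoSampleTResult:
    """Two-sided independent-samples t-test (Student by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("two_sample_t needs at least 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = np.var(a, ddof=1) / n1, np.var(b, ddof=1) / n2
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    return TwoSampleTResult(
        float(res.statistic), df, float(res.pvalue), n1, n2, equal_var
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-based p-value.

    Pairs with a missing value in either variable are dropped (listwise
    deletion); ``n`` is the number of complete pairs actually used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, True)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult(np.nan, np.nan, n, True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, False)
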