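"""Univariate group statistics with the study's effect-size conventions.

Pooled-variance Student t-tests (unpaired, df = n1 + n2 - 2) and paired
t-tests, Pearson product-moment correlation, and Cohen's d. For independent
groups d uses the root-mean-square of the two group SDs as denominator,

    d = (m2 - m1) / sqrt((s1^2 + s2^2) / 2),

which is the convention that reproduces the study's printed effect sizes
(a pooled, df-weighted SD does not). For paired data two candidate
conventions are emitted side by side: mean(diff)/sd(diff) and the RMS-SD
form above; neither is privileged because printed paired effect sizes do
not identify the convention.

Unpaired comparisons accept either raw vectors or (mean, sd, n) summaries,
and the two entry points agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ParameterError, UndefinedStatisticError


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD and n of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("SummaryStats requires n >= 2")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")

    @classmethod
    def from_vector(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ParameterError("need at least 2 non-missing values")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: float
    p: float
    d: float  # mean(diff) / sd(diff)
    d_rms: float  # mean(diff) / rms of the two condition SDs
    n: int


def _coerce(g) -> SummaryStats:
    return g if isinstance(g, SummaryStats) else SummaryStats.from_vector(g)


def cohens_d_independent(g1, g2) -> float:
    """Cohen's d with the RMS-SD denominator, signed as (m2 - m1)."""
    g1, g2 = _coerce(g1), _coerce(g2)
    denom = math.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    if denom == 0.0:
        if g1.mean == g2.mean:
            return 0.0
        raise UndefinedStatisticError("both SDs are zero with unequal means")
    return (g2.mean - g1.mean) / denom


def two_sample_t(g1, g2, welch: bool = False) -> TTestResult:
    """Unpaired Student t-test from raw vectors or summary statistics.

    The statistic is signed as (mean2 - mean1); with the pooled-variance form
    (default) df = n1 + n2 - 2. ``welch=True`` switches to the
    unequal-variance form with Welch-Satterthwaite df. The attached effect
    size is :func:`cohens_d_independent`.
    """
    g1, g2 = _coerce(g1), _coerce(g2)
    diff = g2.mean - g1.mean
    v1, v2 = g1.sd**2, g2.sd**2
    if welch:
        se2 = v1 / g1.n + v2 / g2.n
        if se2 == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, g1.n + g2.n - 2, 1.0, 0.0)
            raise UndefinedStatisticError("zero variance with unequal means")
        df = se2**2 / (
            (v1 / g1.n) ** 2 / (g1.n - 1) + (v2 / g2.n) ** 2 / (g2.n - 1)
        )
        t = diff / math.sqrt(se2)
    else:
        df = g1.n + g2.n - 2
        pooled = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        if pooled == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, df, 1.0, 0.0)
            raise UndefinedStatisticError("zero pooled variance with unequal means")
        t = diff / math.sqrt(pooled * (1.0 / g1.n + 1.0 / g2.n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, d=cohens_d_independent(g1, g2))


def paired_t(x, y) -> PairedTTestResult:
    """Paired Student t-test on the differences ``y - x``.

    ``t = mean(diff) / (sd(diff)/sqrt(n))`` with df = n - 1. Two effect-size
    conventions are reported: ``d`` = mean(diff)/sd(diff) and ``d_rms`` with
    the RMS of the two condition SDs as denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 2:
        raise ParameterError("paired t-test needs at least 2 complete pairs")
    diff = y - x
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedTTestResult(0.0, n - 1, 1.0, 0.0, 0.0, n)
        raise UndefinedStatisticError("zero-variance differences with nonzero mean")
    t = md / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    rms = math.sqrt((x.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2.0)
    d_rms = md / rms if rms > 0 else float("nan")
    return PairedTTestResult(
        t=float(t), df=float(n - 1), p=p, d=md / sd, d_rms=float(d_rms), n=n
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ParameterError("correlation needs at least 3 complete pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedStatisticError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def effect_size_label(d: float) -> str:
    """Conventional |d| interpretation: 0.2 small, 0.5 medium, 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"
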