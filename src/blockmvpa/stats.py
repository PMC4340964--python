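"""Inferential statistics used across the pipeline, built from definitions.

t-tail probabilities are computed through the regularized incomplete beta
function rather than delegating to a packaged t-test, so the oracle tests
can check them against an independent route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import special

Tail = Literal["one", "two"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    tail: Tail
    flagged: bool = False  # degenerate input (zero variance)


def t_sf(t: float | np.ndarray, df: float) -> float | np.ndarray:
    """P(T > t) for Student's t with ``df`` degrees of freedom.

    Uses sf(t) = I_{df/(df+t^2)}(df/2, 1/2) / 2 for t >= 0 and symmetry
    otherwise, with I the regularized incomplete beta function.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        x = df / (df + t**2)
        half_tail = 0.5 * special.betainc(df / 2.0, 0.5, x)
    sf = np.where(t >= 0, half_tail, 1.0 - half_tail)
    sf = np.where(np.isposinf(t), 0.0, sf)
    sf = np.where(np.isneginf(t), 1.0, sf)
    return sf if sf.ndim else float(sf)


def _p_from_t(t: float, df: float, tail: Tail) -> float:
    if tail == "one":
        return float(t_sf(t, df))
    return float(2.0 * t_sf(abs(t), df))


def one_sample_t(values: Sequence[float], null_mean: float = 0.0, tail: Tail = "two") -> TestResult:
    """t = (mean - null_mean) / (sd / sqrt(n)), df = n - 1.

    The one-tailed p is the upper-tail probability (mean > null_mean).
    Zero sample variance yields t = +/-inf (p in {0, 1}) or t = 0 when the
    mean equals the null, flagged either way.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    # relative tolerance: identical values can leave a ~1e-16 residual sd
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        diff = mean - null_mean
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return TestResult(t, df, _p_from_t(t, df, tail), tail, flagged=True)
    t = (mean - null_mean) / (sd / math.sqrt(n))
    return TestResult(float(t), df, _p_from_t(t, df, tail), tail)


def paired_t(x: Sequence[float], y: Sequence[float], tail: Tail = "two") -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0, tail)


def welch_t(x: Sequence[float], y: Sequence[float], tail: Tail = "two") -> TestResult:
    """Two-sample t with unequal variances and Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    scale = max(1.0, float(np.abs(x).max()), float(np.abs(y).max()))
    if se2 <= (1e-12 * scale) ** 2:
        diff = x.mean() - y.mean()
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return TestResult(t, float(n1 + n2 - 2), _p_from_t(t, n1 + n2 - 2, tail), tail, flagged=True)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    return TestResult(float(t), float(df), _p_from_t(t, df, tail), tail)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up procedure.

    Returns (significance flags, p-value threshold).  The threshold is the
    largest p(k) with p(k) <= k*q/m (0.0 when nothing is rejected); all
    p <= threshold are flagged significant.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    ks = np.arange(1, m + 1)
    passing = order <= ks * q / m
    if not passing.any():
        return np.zeros(m, dtype=bool), 0.0
    threshold = order[np.nonzero(passing)[0].max()]
    return p <= threshold, float(threshold)
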