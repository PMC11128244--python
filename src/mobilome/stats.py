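"""Shared statistics kernel: Fisher exact, BH step-up, Welch t.

Thin, contract-enforcing wrappers over scipy/statsmodels so every module
applies the same conventions: two-sided Fisher p-values use the
minimum-likelihood convention (sum of hypergeometric probabilities of all
tables with the same margins no more probable than the observed one), and
odds ratios are reported with a Haldane–Anscombe 0.5 correction for
display only, never for testing.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The all-zero table has no information; by convention p = 1 (with a
    warning).
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
    if a + b + c + d == 0:
        warnings.warn("Fisher exact on an all-zero table; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    p = float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return min(p, 1.0)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with Haldane–Anscombe correction when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return [float(x) for x in q]


def welch_t_two_sided(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sided t-test; returns (t, Welch–Satterthwaite df, p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must have size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    res = _sps.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / len(x), vy / len(y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def binomial_ci_95(k: int, n: int) -> tuple[float, float]:
    """Normal-approximation 95% interval for a proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    half = 1.96 * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))
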