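"""Statistical kernel: Wilson intervals, prevalence ratios, chi-squared tests.

Two confidence-interval procedures are the core of the reporting layer:

* **Wilson score interval** for a binomial proportion x/n at confidence
  level ``conf``: with :math:`z` the standard-normal quantile and
  :math:`\\hat p = x/n`, the interval is centred at
  :math:`(x + z^2/2)/(n + z^2)` with half-width
  :math:`z\\sqrt{\\hat p(1-\\hat p)/n + z^2/4n^2}/(1 + z^2/n)`.
  No continuity correction is applied.

* **Katz log-method interval** for the ratio of two independent binomial
  proportions :math:`PR = (x_1/n_1)/(x_2/n_2)`:
  :math:`\\exp(\\ln PR \\pm z\\sqrt{(1-p_1)/x_1 + (1-p_2)/x_2})`.

Chi-squared tests are Pearson tests on contingency tables of counts,
without continuity correction. Display rounding is half-away-from-zero;
internal values are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ProportionCI:
    x: int
    n: int
    p: float
    lo: float
    hi: float
    conf: float = 0.95


@dataclass(frozen=True)
class PrevalenceRatioResult:
    x1: int
    n1: int
    x2: int
    n2: int
    pr: float
    lo: float
    hi: float
    conf: float = 0.95


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray


def _z(conf: float) -> float:
    return float(sps.norm.ppf(0.5 + conf / 2.0))


def wilson_bounds(x, n, conf: float = 0.95):
    """Vectorised Wilson score bounds; returns ``(lo, hi)`` arrays."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    z = _z(conf)
    p = x / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = (z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))) / denom
    lo = np.clip(centre - half, 0.0, 1.0)
    hi = np.clip(centre + half, 0.0, 1.0)
    # the bounds are analytically exact at the extremes; avoid FP residue
    lo = np.where(x == 0, 0.0, lo)
    hi = np.where(x == n, 1.0, hi)
    return lo, hi


def wilson_ci(x: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion, no continuity correction."""
    if n < 1:
        raise ValueError("wilson_ci: n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("wilson_ci: require 0 <= x <= n")
    lo, hi = wilson_bounds(x, n, conf)
    return ProportionCI(x=x, n=n, p=x / n, lo=float(lo), hi=float(hi), conf=conf)


def prevalence_ratio(x1: int, n1: int, x2: int, n2: int, conf: float = 0.95) -> PrevalenceRatioResult:
    """Ratio of two binomial proportions with a Katz log-method CI.

    ``(x1, n1)`` is the numerator cohort, ``(x2, n2)`` the reference.
    ``x2 = 0`` leaves the ratio undefined and is an error; ``x1 = 0``
    yields ``pr = 0`` with a degenerate lower bound of 0 and the upper
    bound from the 0.5-substitution rule (approximate).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("prevalence_ratio: denominators must be >= 1")
    if x2 == 0:
        raise ValueError("prevalence_ratio: reference numerator x2 = 0, ratio undefined")
    p2 = x2 / n2
    z = _z(conf)
    if x1 == 0:
        # substitute 0.5 for the upper bound only; flagged approximate
        p1s = 0.5 / n1
        se = math.sqrt((1.0 - p1s) / 0.5 + (1.0 - p2) / x2)
        hi = math.exp(math.log((p1s) / p2) + z * se)
        return PrevalenceRatioResult(x1, n1, x2, n2, pr=0.0, lo=0.0, hi=hi, conf=conf)
    p1 = x1 / n1
    pr = p1 / p2
    se = math.sqrt((1.0 - p1) / x1 + (1.0 - p2) / x2)
    lo = math.exp(math.log(pr) - z * se)
    hi = math.exp(math.log(pr) + z * se)
    return PrevalenceRatioResult(x1, n1, x2, n2, pr=pr, lo=lo, hi=hi, conf=conf)


def chi_squared(table) -> ChiSquareResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi_squared: need a table with >= 2 rows and >= 2 columns")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    if (row_tot == 0).any():
        bad = int(np.flatnonzero(row_tot == 0)[0])
        raise ValueError(f"chi_squared: row {bad} has zero marginal total")
    if (col_tot == 0).any():
        bad = int(np.flatnonzero(col_tot == 0)[0])
        raise ValueError(f"chi_squared: column {bad} has zero marginal total")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p_value=float(p), table=table)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def format_percent(p: float) -> str:
    """Format a proportion as the tables print it.

    Proportions of at least 10% are given to the nearest percentage
    point; below 10% one decimal place is kept (e.g. ``5.7%``).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("format_percent: proportion must lie in [0, 1]")
    pct = p * 100.0
    if p < 0.10:
        return f"{round_half_away(pct, 1):.1f}%"
    return f"{round_half_away(pct, 0):.0f}%"


def format_ratio(r: float) -> str:
    return f"{round_half_away(r, 2):.2f}"
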