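"""Prevalence estimates and the 2x2 chi-square comparison.

Prevalences are reported in percent with a normal-approximation (Wald)
95% interval, p-hat +/- z * sqrt(p-hat (1 - p-hat) / n); the Wilson score
interval is available as an alternative. The incidence comparison between
exposure groups uses the Pearson chi-square test on the 2x2 table, with the
Yates continuity correction optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["ProportionEstimate", "ChiSquareResult", "proportion_ci", "chi_square_2x2"]


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its confidence interval, all on the percent scale."""

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "wald"


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    corrected: bool


def proportion_ci(
    numerator: int,
    denominator: int,
    level: float = 0.95,
    method: str = "wald",
) -> ProportionEstimate:
    """Point estimate and CI for a binomial proportion, in percent.

    The Wald interval can extend below 0% or above 100% for proportions near
    the boundary; it is deliberately not clipped, matching how such intervals
    are conventionally printed alongside small prevalences.
    """
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError(f"numerator {numerator} outside [0, {denominator}]")
    p = numerator / denominator
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / denominator)
        lo, hi = p - half, p + half
    elif method == "wilson":
        n = denominator
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = (z / (1 + z**2 / n)) * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
        lo, hi = centre - half, centre + half
    else:
        raise ValidationError(f"unknown CI method {method!r}; expected 'wald' or 'wilson'")
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        percent=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        level=level,
        method=method,
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a 2x2 table.

    Table layout: rows are exposure groups, columns are event / no event::

        exposed      a   b
        unexposed    c   d

    The statistic is ``N (|ad - bc| - corr)^2 / ((a+b)(c+d)(a+c)(b+d))`` with
    ``corr = N/2`` under the Yates correction and 0 otherwise; p is the upper
    tail of chi-square with one degree of freedom.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValidationError(f"negative cell count in {counts}")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValidationError(f"zero margin in 2x2 table {counts}")
    delta = abs(a * d - b * c)
    if correction:
        delta = max(delta - n / 2, 0.0)
    statistic = n * delta**2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=float(statistic), df=1, p=p, corrected=correction)
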