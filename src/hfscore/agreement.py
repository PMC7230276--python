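"""Inter-observer agreement via intraclass correlation coefficients.

Two readers scoring the same patients are treated as interchangeable raters
drawn from a population of raters, so the default form is ICC(2,1): two-way
random effects, absolute agreement, single measurement,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE)),

where MSR, MSC and MSE are the subject, rater and residual mean squares from
a two-way ANOVA without replication on the n x k ratings matrix. ICC(3,1)
(two-way mixed, consistency) is available for the case where the specific
raters are the only raters of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["ICCResult", "icc", "anova_mean_squares"]


@dataclass(frozen=True)
class ICCResult:
    """An ICC point estimate with the ANOVA mean squares behind it."""

    estimate: float
    model: str  # "icc2" or "icc3"
    n_subjects: int
    n_raters: int
    msr: float  # between-subject mean square
    msc: float  # between-rater mean square
    mse: float  # residual mean square
    ci_low: float | None = None
    ci_high: float | None = None


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (subjects, raters, residual) of a two-way layout without replication."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    values: np.ndarray,
    model: str = "icc2",
    ci: bool = False,
    level: float = 0.95,
) -> ICCResult:
    """Intraclass correlation of an ``n x k`` complete ratings matrix.

    Parameters
    ----------
    values
        ``n`` subjects by ``k`` raters, no missing cells.
    model
        ``"icc2"`` for ICC(2,1) (two-way random, absolute agreement, default)
        or ``"icc3"`` for ICC(3,1) (two-way mixed, consistency).
    ci
        If true, attach an F-based confidence interval (Shrout & Fleiss).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"ratings matrix must be 2-D, got shape {x.shape}")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >=2 subjects and >=2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ratings matrix has missing or non-finite cells")
    if model not in ("icc2", "icc3"):
        raise ValidationError(f"unknown ICC model {model!r}; expected 'icc2' or 'icc3'")

    msr, msc, mse = anova_mean_squares(x)
    if msr <= mse:
        warnings.warn(
            "between-subject variance does not exceed residual variance;"
            " ICC estimate is <= 0",
            stacklevel=2,
        )

    if model == "icc2":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom if denom > 0 else 0.0
    else:
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else 0.0

    lo = hi = None
    if ci:
        lo, hi = _f_ci(model, est, msr, msc, mse, n, k, level)
    return ICCResult(
        estimate=float(est),
        model=model,
        n_subjects=n,
        n_raters=k,
        msr=msr,
        msc=msc,
        mse=mse,
        ci_low=lo,
        ci_high=hi,
    )


def _f_ci(model, est, msr, msc, mse, n, k, level):
    """Shrout & Fleiss F-based interval. ICC(2,1) uses the Satterthwaite df."""
    alpha = 1.0 - level
    if model == "icc3":
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(lo), float(hi)
    # ICC(2,1): Satterthwaite approximation for the denominator df
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_star_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star_l * msr
    )
    return float(lo), float(hi)
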