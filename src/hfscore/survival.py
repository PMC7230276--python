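"""Time-to-event machinery: Kaplan-Meier, trend log-rank, Cox regression.

All three are implemented directly on the usual counting-process quantities.
Let tau_1 < tau_2 < ... be the distinct event times, d_j the number of events
at tau_j and n_j the number at risk just before tau_j.

* Kaplan-Meier: the product-limit estimator S(t) = prod_{tau_j <= t} (1 - d_j / n_j).

* Trend log-rank: each subject carries an ordinal group score s. With
  U = sum_j (sum of event scores at tau_j - d_j * mean risk-set score) and the
  hypergeometric variance V = sum_j [d_j (n_j - d_j) / (n_j - 1)] *
  [mean of s^2 in risk set - (mean s)^2], the statistic U^2 / V is chi-square
  with one degree of freedom under the null of no trend. With two groups
  scored 0/1 this reduces to the ordinary two-sample log-rank test.

* Cox proportional hazards: the partial likelihood is maximised by
  Newton-Raphson with analytic gradient and Hessian; tied event times are
  handled by the Breslow approximation by default, with Efron optional.
  Standard errors come from the inverse observed information and confidence
  intervals are Wald intervals exponentiated to the hazard-ratio scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "CENSOR_REASONS",
    "KMCurve",
    "FitResult",
    "CoxFit",
    "km_estimate",
    "trend_logrank",
    "cox_fit",
    "cox_score_test",
    "replaced_multiple",
]

#: Recognised censoring-reason tokens for a cohort record. ``none`` marks events.
CENSOR_REASONS = ("death", "transfer", "lost", "ici_initiation", "admin_end", "none")


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    n_at_risk: np.ndarray  # at risk just before each event time
    n_events: np.ndarray  # events at each event time
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """S(t) (right-continuous step function; S = 1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_incidence_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)


def _check_times(time: np.ndarray) -> None:
    if len(time) == 0:
        raise ValidationError("need at least one record")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValidationError("follow-up times must be positive and finite")


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate from follow-up times and event indicators."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    _check_times(t)
    event_times = np.unique(t[d])
    n_at_risk = np.array([(t >= tau).sum() for tau in event_times], dtype=float)
    n_events = np.array([(d & (t == tau)).sum() for tau in event_times], dtype=float)
    if len(event_times) == 0:
        return KMCurve(
            times=event_times,
            n_at_risk=n_at_risk,
            n_events=n_events,
            survival=np.array([]),
        )
    survival = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(
        times=event_times, n_at_risk=n_at_risk, n_events=n_events, survival=survival
    )


# ---------------------------------------------------------------------------
# Trend log-rank


@dataclass(frozen=True)
class TrendLogrankResult:
    statistic: float
    p: float
    u: float  # observed-minus-expected score sum
    variance: float
    df: int = 1


def trend_logrank(time, event, scores) -> TrendLogrankResult:
    """Log-rank test for trend across ordered groups.

    ``scores`` assigns each subject the ordinal score of its group (e.g.
    0, 1, 2 for three ordered risk strata). The statistic is invariant to
    affine transforms of the scores.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_times(t)
    if len({round(v, 12) for v in s}) < 2:
        raise ValidationError("need at least two distinct group scores")

    u = 0.0
    var = 0.0
    for tau in np.unique(t[d]):
        at_risk = t >= tau
        n_j = at_risk.sum()
        events_here = d & (t == tau)
        d_j = events_here.sum()
        s_risk = s[at_risk]
        mean_s = s_risk.mean()
        u += s[events_here].sum() - d_j * mean_s
        if n_j > 1:
            var += (
                d_j
                * (n_j - d_j)
                / (n_j - 1)
                * ((s_risk**2).mean() - mean_s**2)
            )
    if var <= 0:
        raise ValidationError("trend log-rank variance is zero (scores constant in risk sets)")
    statistic = u**2 / var
    return TrendLogrankResult(
        statistic=float(statistic),
        p=float(stats.chi2.sf(statistic, df=1)),
        u=float(u),
        variance=float(var),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class FitResult:
    """One fitted coefficient on both the log-hazard and hazard-ratio scales."""

    name: str
    estimate: float  # log hazard ratio
    hr: float
    se: float
    ci_low: float  # on the HR scale
    ci_high: float
    p: float
    n_events: int
    converged: bool


@dataclass(frozen=True)
class CoxFit:
    coefficients: list[FitResult]
    loglik: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    converged: bool
    covariance: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, name: str) -> FitResult:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": c.name,
                    "coef": c.estimate,
                    "hr": c.hr,
                    "se": c.se,
                    "hr_ci_low": c.ci_low,
                    "hr_ci_high": c.ci_high,
                    "p": c.p,
                }
                for c in self.coefficients
            ]
        ).set_index("covariate")


def _partial_lik_derivs(beta, t, d, X, ties):
    """Log partial likelihood, score vector and observed information.

    Uses suffix sums over subjects sorted by ascending time so each risk set
    is a contiguous tail of the sorted arrays.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)  # guard exp overflow during divergence
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)

    # suffix sums: S0[i] = sum_{k >= i} w_k etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(t[d])
    for tau in event_times:
        i0 = np.searchsorted(t, tau, side="left")
        events_here = d & (t == tau)
        d_j = int(events_here.sum())
        s_j = X[events_here].sum(axis=0)
        loglik += float(eta[events_here].sum())
        s0, s1, s2 = S0[i0], S1[i0], S2[i0]
        if ties == "breslow" or d_j == 1:
            loglik -= d_j * np.log(s0)
            mu = s1 / s0
            score += s_j - d_j * mu
            info += d_j * (s2 / s0 - np.outer(mu, mu))
        else:  # efron
            w_d = w[events_here].sum()
            s1_d = wx[events_here].sum(axis=0)
            s2_d = wxx[events_here].sum(axis=0)
            for l in range(d_j):
                f = l / d_j
                s0_l = s0 - f * w_d
                s1_l = s1 - f * s1_d
                s2_l = s2 - f * s2_d
                loglik -= np.log(s0_l)
                mu = s1_l / s0_l
                score += s_j / d_j - mu
                info += s2_l / s0_l - np.outer(mu, mu)
    return loglik, score, info


def _prepare(time, event, X):
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _check_times(t)
    if d.sum() == 0:
        raise ValidationError("no events: Cox model is not estimable")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate column {j} is constant (non-identifiable)")
    order = np.argsort(t, kind="stable")
    return t[order], d[order], X[order]


def cox_fit(
    time,
    event,
    X,
    names: list[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 50,
    score_tol: float = 1e-9,
    step_tol: float = 1e-10,
    level: float = 0.95,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    time, event
        Follow-up time (positive) and event indicator per subject.
    X
        Covariate matrix, one column per covariate (a 1-D array is treated
        as a single covariate).
    ties
        ``"breslow"`` (default) or ``"efron"`` handling of tied event times.
    """
    if ties not in ("breslow", "efron"):
        raise ValidationError(f"unknown tie method {ties!r}")
    t, d, Xs = _prepare(time, event, X)
    n, p = Xs.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValidationError(f"{len(names)} names for {p} covariates")

    # centre and scale for numerical stability; transform back afterwards
    centre = Xs.mean(axis=0)
    scale = Xs.std(axis=0)
    Z = (Xs - centre) / scale

    beta = np.zeros(p)
    loglik, g, info = _partial_lik_derivs(beta, t, d, Z, ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            raise ValidationError(
                "singular information matrix (collinear covariates?)"
            ) from None
        # step halving if the likelihood does not improve
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, info_new = _partial_lik_derivs(cand, t, d, Z, ties)
            if ll_new >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, g, info = cand, ll_new, g_new, info_new
        if np.max(np.abs(g)) < score_tol or np.max(np.abs(factor * step)) < step_tol:
            converged = True
            break

    try:
        cov_z = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ValidationError("singular information matrix at the optimum") from None

    # monotone (separated) partial likelihood: the score plateaus to zero while
    # the standardised coefficient runs away and the information collapses
    se_z = np.sqrt(np.abs(np.diag(cov_z)))
    diverged = np.max(np.abs(beta)) > 10.0 or np.max(se_z) > 10.0
    if diverged:
        warnings.warn(
            "Cox fit did not converge: monotone partial likelihood"
            " (complete separation of risk sets); estimates capped",
            stacklevel=2,
        )
        beta = np.clip(beta, -10.0, 10.0)
        converged = False
    if not converged and not diverged:
        warnings.warn(f"Cox fit did not converge in {max_iter} iterations", stacklevel=2)
    # back-transform to the original covariate scale
    beta_orig = beta / scale
    cov = cov_z / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov))
    z_crit = stats.norm.ppf(0.5 + level / 2)
    n_events = int(d.sum())
    coefs = []
    for j in range(p):
        b, s = float(beta_orig[j]), float(se[j])
        zstat = b / s if s > 0 else np.inf
        _exp = lambda v: float(np.exp(min(v, 700.0)))  # inf-safe on capped fits
        coefs.append(
            FitResult(
                name=names[j],
                estimate=b,
                hr=_exp(b),
                se=s,
                ci_low=_exp(b - z_crit * s),
                ci_high=_exp(b + z_crit * s),
                p=float(2 * stats.norm.sf(abs(zstat))),
                n_events=n_events,
                converged=converged,
            )
        )
    return CoxFit(
        coefficients=coefs,
        loglik=float(loglik),
        n=n,
        n_events=n_events,
        ties=ties,
        n_iter=n_iter,
        converged=converged,
        covariance=cov,
    )


def cox_score_test(time, event, X, ties: str = "breslow") -> TrendLogrankResult:
    """Score (Rao) test of beta = 0 in the Cox model.

    For a single binary covariate without tie corrections this is identical
    to the two-sample log-rank test.
    """
    t, d, Xs = _prepare(time, event, X)
    Z = Xs - Xs.mean(axis=0)
    _, u, info = _partial_lik_derivs(np.zeros(Z.shape[1]), t, d, Z, ties)
    try:
        statistic = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        raise ValidationError("singular information matrix at beta = 0") from None
    df = Z.shape[1]
    return TrendLogrankResult(
        statistic=statistic,
        p=float(stats.chi2.sf(statistic, df=df)),
        u=float(u[0]) if df == 1 else float(np.nan),
        variance=float(info[0, 0]) if df == 1 else float(np.nan),
        df=df,
    )


def replaced_multiple(
    time,
    event,
    primary,
    adjusters: dict[str, np.ndarray | pd.DataFrame],
    primary_name: str = "hfs",
    ties: str = "breslow",
) -> pd.DataFrame:
    """Bivariable sensitivity analysis for one primary covariate.

    Each adjuster is entered alongside the primary covariate in its own
    two-covariate (bivariable) Cox model and the primary coefficient is
    reported from every model, showing how stable the primary effect is to
    one-at-a-time adjustment. Multi-column adjusters (dummy-coded factors)
    are supported.
    """
    primary = np.asarray(primary, dtype=float)
    rows = []
    for adj_name, cols in adjusters.items():
        A = np.asarray(cols, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        Xfull = np.column_stack([primary, A])
        names = [primary_name] + [f"{adj_name}_{k}" for k in range(A.shape[1])]
        fit = cox_fit(time, event, Xfull, names=names, ties=ties)
        c = fit[primary_name]
        rows.append(
            {
                "adjuster": adj_name,
                "hr": c.hr,
                "hr_ci_low": c.ci_low,
                "hr_ci_high": c.ci_high,
                "p": c.p,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("adjuster")
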