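"""Cohort-level analysis tables and figures.

Renders, for any cohort table in the standard schema:

* a baseline-characteristics table (counts and percentages);
* a prevalence table (pre-existing ILD; drug-induced pneumonitis overall and
  split by ILD status, with the chi-square comparison);
* the simple-Cox risk-factor table (one model per candidate factor, dummy
  coding against the cohort's reference levels, ``n/c`` where a level has no
  events);
* the replaced-multiple table (the HFS coefficient from each bivariable
  {HFS, adjuster} model);
* a stacked-bar figure of events by score and a cumulative-incidence
  Kaplan-Meier figure by HFS stratum annotated with the trend log-rank p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_stats import chi_square_2x2, proportion_ci
from .errors import ValidationError
from .io import fmt_ci, fmt_hr, fmt_percent
from .scoring import hfs_stratum
from .survival import cox_fit, km_estimate, replaced_multiple, trend_logrank

__all__ = [
    "build_covariates",
    "table1",
    "prevalence_table",
    "simple_cox_table",
    "replaced_multiple_table",
    "km_figure",
    "score_bar_figure",
]

#: Risk stratum labels in increasing-risk order with their ordinal scores.
STRATA = ("eq100", "gt100_le110", "gt110")


def build_covariates(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dummy-coded analysis covariates with the conventional reference levels.

    References: age < 70, female, PS 0-1, adenocarcinoma, stage III,
    never-smoker, no gene abnormality, no operation, no radiation. Clinical
    stages I and II are pooled into one indicator. HFS enters centred at 100
    (the per-point hazard ratio is unchanged by centring).
    """
    c = cohort
    return {
        "hfs_centered": c["hfs"].to_numpy(float) - 100.0,
        "gs": c["gs"].to_numpy(float),
        "age_ge70": (c["age"].to_numpy(float) >= 70).astype(float),
        "male": (c["sex"] == "male").to_numpy(float),
        "ps_2_4": (c["ecog_ps"] == "2-4").to_numpy(float),
        "ever_smoker": (c["smoking"] == "ever").to_numpy(float),
        "hist_squamous": (c["histology"] == "squamous").to_numpy(float),
        "hist_sclc": (c["histology"] == "sclc").to_numpy(float),
        "hist_other": (c["histology"] == "other").to_numpy(float),
        "stage_I_II": c["stage"].isin(["I", "II"]).to_numpy(float),
        "stage_IV_rec": (c["stage"] == "IV_rec").to_numpy(float),
        "gene_abnormal": c["gene_abnormality"].astype(bool).to_numpy(float),
        "operation": c["operation"].astype(bool).to_numpy(float),
        "radiation": c["radiation"].astype(bool).to_numpy(float),
    }


#: Simple-Cox table layout: (variable, [(row label, covariate key | None for reference)]).
_SIMPLE_COX_LAYOUT = [
    ("Age", [("< 70", None), (">= 70", "age_ge70")]),
    ("Sex", [("Female", None), ("Male", "male")]),
    ("ECOG-PS", [("0-1", None), ("2-4", "ps_2_4")]),
    ("Histology", [("Adenocarcinoma", None), ("Squamous", "hist_squamous"),
                   ("Small-cell", "hist_sclc"), ("Others", "hist_other")]),
    ("Clinical stage", [("I-II", "stage_I_II"), ("III", None), ("IV, recurrence", "stage_IV_rec")]),
    ("Smoking history", [("Never", None), ("Ever", "ever_smoker")]),
    ("Gene abnormality", [("No", None), ("Yes", "gene_abnormal")]),
    ("GS (per point)", [("GS (per point)", "gs")]),
    ("HFS (per point)", [("HFS (per point)", "hfs_centered")]),
    ("Operation", [("No", None), ("Yes", "operation")]),
    ("Radiation", [("No", None), ("Yes", "radiation")]),
]

#: Adjusters entered one at a time alongside HFS in the bivariable models.
_ADJUSTERS = [
    ("Age", ["age_ge70"]),
    ("Sex", ["male"]),
    ("ECOG-PS", ["ps_2_4"]),
    ("Histology", ["hist_squamous", "hist_sclc", "hist_other"]),
    ("Clinical stage", ["stage_I_II", "stage_IV_rec"]),
    ("Smoking history", ["ever_smoker"]),
    ("Gene abnormality", ["gene_abnormal"]),
    ("GS", ["gs"]),
    ("Operation", ["operation"]),
    ("Radiation", ["radiation"]),
]


def table1(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics: count (percent) per category."""
    n = len(cohort)

    def pct_row(label, mask):
        k = int(mask.sum())
        return {"characteristic": label, "value": f"{k} ({100.0 * k / n:.0f}%)"}

    rows = [
        {
            "characteristic": "Age, median (range)",
            "value": f"{cohort['age'].median():.0f}"
                     f" ({cohort['age'].min()}-{cohort['age'].max()})",
        },
        pct_row("Male", cohort["sex"] == "male"),
        pct_row("Ever-smoker", cohort["smoking"] == "ever"),
        pct_row("ECOG-PS 2-4", cohort["ecog_ps"] == "2-4"),
    ]
    for h in ("adeno", "squamous", "sclc", "other"):
        rows.append(pct_row(f"Histology: {h}", cohort["histology"] == h))
    for s in ("I", "II", "III", "IV_rec"):
        rows.append(pct_row(f"Stage: {s}", cohort["stage"] == s))
    rows.append(pct_row("Gene abnormality", cohort["gene_abnormality"].astype(bool)))
    gs = cohort["gs"].to_numpy(float)
    rows.append(pct_row("GS 0 (none)", pd.Series(gs == 0)))
    rows.append(pct_row("GS 1-7 (mild)", pd.Series((gs >= 1) & (gs <= 7))))
    rows.append(pct_row("GS 8-15 (moderate)", pd.Series((gs >= 8) & (gs <= 15))))
    rows.append(pct_row("GS 16-24 (severe)", pd.Series(gs >= 16)))
    rows.append(pct_row("Pre-existing ILD (HFS > 100)", cohort["hfs"] > 100))
    return pd.DataFrame(rows).set_index("characteristic")


def prevalence_table(cohort: pd.DataFrame, ci_method: str = "wald") -> pd.DataFrame:
    """ILD and pneumonitis prevalences with 95% CIs, plus the 2x2 chi-square."""
    n = len(cohort)
    ild = cohort["hfs"] > 100
    ev = cohort["event"].astype(bool)
    rows = []

    def add(label, num, den):
        est = proportion_ci(num, den, method=ci_method)
        rows.append(
            {
                "quantity": label,
                "n": f"{num}/{den}",
                "percent": fmt_percent(est.percent),
                "ci95": fmt_ci(est.ci_low, est.ci_high, fmt_percent),
            }
        )

    add("Pre-existing ILD", int(ild.sum()), n)
    add("Drug-induced pneumonitis", int(ev.sum()), n)
    add("Pneumonitis | ILD", int((ev & ild).sum()), int(ild.sum()))
    add("Pneumonitis | no ILD", int((ev & ~ild).sum()), int((~ild).sum()))
    chi = chi_square_2x2(
        int((ev & ild).sum()), int((~ev & ild).sum()),
        int((ev & ~ild).sum()), int((~ev & ~ild).sum()),
    )
    rows.append(
        {
            "quantity": "Chi-square (pneumonitis by ILD)",
            "n": "",
            "percent": f"{chi.statistic:.2f}",
            "ci95": f"p = {chi.p:.2e}" if chi.p >= 1e-4 else "p < 0.0001",
        }
    )
    return pd.DataFrame(rows).set_index("quantity")


def simple_cox_table(cohort: pd.DataFrame, ties: str = "breslow") -> pd.DataFrame:
    """One simple Cox model per candidate risk factor.

    Factor levels with zero events are flagged ``n/c`` (not calculable) and
    removed from that factor's model rather than silently dropped.
    """
    cov = build_covariates(cohort)
    time = cohort["time_days"].to_numpy(float)
    event = cohort["event"].astype(bool).to_numpy()
    rows = []
    for variable, levels in _SIMPLE_COX_LAYOUT:
        keys = [k for _, k in levels if k is not None]
        estimable, dropped = [], []
        for k in keys:
            x = cov[k]
            is_indicator = set(np.unique(x)) <= {0.0, 1.0}
            if is_indicator and event[x == 1].sum() == 0:
                dropped.append(k)
            else:
                estimable.append(k)
        fit = None
        if estimable:
            X = np.column_stack([cov[k] for k in estimable])
            fit = cox_fit(time, event, X, names=estimable, ties=ties)
        for label, k in levels:
            if k is None:
                rows.append({"variable": variable, "level": label, "hr": "1.00",
                             "ci95": "", "p": "", "note": "reference"})
            elif k in dropped:
                rows.append({"variable": variable, "level": label, "hr": "n/c",
                             "ci95": "", "p": "", "note": "no events at this level"})
            else:
                c = fit[k]
                rows.append(
                    {
                        "variable": variable,
                        "level": label,
                        "hr": fmt_hr(c.hr),
                        "ci95": fmt_ci(c.ci_low, c.ci_high),
                        "p": "< 0.0001" if c.p < 1e-4 else f"{c.p:.3g}",
                        "note": "" if c.converged else "did not converge",
                    }
                )
    return pd.DataFrame(rows).set_index(["variable", "level"])


def replaced_multiple_table(cohort: pd.DataFrame, ties: str = "breslow") -> pd.DataFrame:
    """HFS per-point HR from each bivariable {HFS, adjuster} model."""
    cov = build_covariates(cohort)
    time = cohort["time_days"].to_numpy(float)
    event = cohort["event"].astype(bool).to_numpy()
    adjusters = {
        name: np.column_stack([cov[k] for k in keys]) for name, keys in _ADJUSTERS
    }
    raw = replaced_multiple(
        time, event, cov["hfs_centered"], adjusters, primary_name="hfs", ties=ties
    )
    simple = cox_fit(time, event, cov["hfs_centered"], names=["hfs"], ties=ties)["hfs"]
    rows = [
        {
            "adjuster": "(simple)",
            "hfs_hr": fmt_hr(simple.hr),
            "ci95": fmt_ci(simple.ci_low, simple.ci_high),
            "p": "< 0.0001" if simple.p < 1e-4 else f"{simple.p:.3g}",
        }
    ]
    for adj, row in raw.iterrows():
        rows.append(
            {
                "adjuster": adj,
                "hfs_hr": fmt_hr(row["hr"]),
                "ci95": fmt_ci(row["hr_ci_low"], row["hr_ci_high"]),
                "p": "< 0.0001" if row["p"] < 1e-4 else f"{row['p']:.3g}",
            }
        )
    return pd.DataFrame(rows).set_index("adjuster")


def strata_scores(cohort: pd.DataFrame, cutoffs=(100.0, 110.0)) -> np.ndarray:
    """Ordinal 0/1/2 score of each patient's HFS risk stratum."""
    labels = [hfs_stratum(h, cutoffs) for h in cohort["hfs"]]
    return np.array([STRATA.index(s) for s in labels], dtype=float)


def km_figure(cohort: pd.DataFrame, cutoffs=(100.0, 110.0)):
    """Cumulative incidence of pneumonitis by HFS stratum, with trend p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = strata_scores(cohort, cutoffs)
    time = cohort["time_days"].to_numpy(float)
    event = cohort["event"].astype(bool).to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4.5))
    pretty = {"eq100": f"HFS = {cutoffs[0]:g}",
              "gt100_le110": f"{cutoffs[0]:g} < HFS ≤ {cutoffs[1]:g}",
              "gt110": f"HFS > {cutoffs[1]:g}"}
    for idx, label in enumerate(STRATA):
        mask = scores == idx
        if mask.sum() == 0:
            continue
        curve = km_estimate(time[mask], event[mask])
        last = 1.0 - (curve.survival[-1] if len(curve.survival) else 1.0)
        ts = np.concatenate([[0.0], curve.times, [time.max()]])
        inc = np.concatenate([[0.0], 1.0 - curve.survival, [last]])
        ax.step(ts, inc, where="post", label=f"{pretty[label]} (n={int(mask.sum())})")
    try:
        p = trend_logrank(time, event, scores).p
        note = "p < 0.0001" if p < 1e-4 else f"p = {p:.3g}"
        ax.set_title(f"Cumulative incidence of drug-induced pneumonitis (trend log-rank {note})")
    except ValidationError:
        ax.set_title("Cumulative incidence of drug-induced pneumonitis")
    ax.set_xlabel("Days from first anti-cancer drug")
    ax.set_ylabel("Cumulative incidence")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def score_bar_figure(cohort: pd.DataFrame):
    """Stacked bars of patients with/without pneumonitis by HFS and by GS."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    event = cohort["event"].astype(bool).to_numpy()
    fig, axes = plt.subplots(2, 1, figsize=(7, 6))
    for ax, col, width, label in (
        (axes[0], "hfs", 0.8, "HFS (points)"),
        (axes[1], "gs", 0.6, "Goddard score (points)"),
    ):
        vals = cohort[col].to_numpy(float)
        uniq = np.unique(vals)
        no_ev = [np.sum((vals == v) & ~event) for v in uniq]
        ev = [np.sum((vals == v) & event) for v in uniq]
        ax.bar(uniq, no_ev, width=width, color="black", label="no pneumonitis")
        ax.bar(uniq, ev, width=width, bottom=no_ev, color="red", label="pneumonitis")
        ax.set_xlabel(label)
        ax.set_ylabel("Patients")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
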