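"""Synthetic cohorts and reader data with the structure the analysis assumes.

The generator emulates a single-institution lung-cancer chemotherapy cohort:

* ~28.5% of patients have pre-existing ILD (HFS > 100); all of it mild, with
  the HFS excess over 100 drawn from a truncated exponential and rounded onto
  the 5/6-point lattice that six-region 5%-grid arithmetic can actually
  produce (region scores are multiples of 5; a reader HFS is their mean).
* covariate marginals follow the cohort table of the study population
  (two thirds male, two thirds ever-smokers, mostly adenocarcinoma, two
  percent poor performance status, and so on), drawn independently.
* drug-induced pneumonitis times are exponential with hazard
  ``lambda0 * exp(beta_hfs * (HFS - 100))`` - log-linear in the HFS excess -
  and are censored by an administrative horizon plus an independent dropout
  process (death, hospital transfer, loss to follow-up, or switch to immune
  checkpoint inhibitors).
* two readers re-derive each patient's scores from region-level reads with
  discrete noise on the 5% extent grid.

Two quantities are calibrated deterministically rather than guessed:

* the baseline hazard ``lambda0`` is solved (Brent root-finding on the exact
  event-probability integral over the lattice HFS distribution) so that the
  expected event fraction matches a target (default 19/214);
* the reader-noise scale is solved so that the population intraclass
  correlation of the two readers' HFS - computed exactly by enumerating the
  discrete noise kernel per patient, truncation included - equals a target
  (default 0.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .scoring import REGION_IDS

__all__ = [
    "CohortSpec",
    "ReaderNoiseSpec",
    "simulate_cohort",
    "simulate_reads",
    "simulate_ratings",
    "calibrate_baseline_hazard",
    "calibrate_noise_scale",
    "LATTICE_STEP",
]

#: Smallest positive HFS excess reachable by one reader: one 5% step in one
#: of six regions moves the reader mean by 5/6 of a point.
LATTICE_STEP = 5.0 / 6.0

_DEFAULT_HISTOLOGY = {"adeno": 136 / 214, "squamous": 35 / 214, "sclc": 31 / 214, "other": 12 / 214}
_DEFAULT_STAGE = {"I": 4 / 214, "II": 14 / 214, "III": 53 / 214, "IV_rec": 143 / 214}
_DEFAULT_GS_CATS = {"none": 93 / 214, "mild": 77 / 214, "moderate": 36 / 214, "severe": 8 / 214}
_GS_BANDS = {"none": (0, 0), "mild": (1, 7), "moderate": (8, 15), "severe": (16, 24)}
_DROPOUT_REASONS = ("death", "transfer", "lost", "ici_initiation")
_DROPOUT_REASON_P = (0.60, 0.15, 0.10, 0.15)

#: Basal-to-apical region order: fibrosis predominates in the lower zones,
#: emphysema in the upper zones, so remainders are assigned accordingly.
_BASAL_FIRST = ("ipv_R", "ipv_L", "mid_R", "mid_L", "carina_R", "carina_L")
_APICAL_FIRST = tuple(reversed(_BASAL_FIRST))


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``baseline_hazard=None`` means "calibrate so that the expected event
    fraction equals ``target_event_fraction``".
    """

    n: int = 214
    p_ild: float = 61 / 214
    hfs_excess_mean: float = 15.0  # mean of the truncated exponential, points
    hfs_excess_max: float = 100.0  # truncation bound (all synthetic ILD is mild)
    beta_hfs: float = float(np.log(1.16))  # true log hazard ratio per HFS point
    baseline_hazard: float | None = None  # events per day at HFS = 100
    target_event_fraction: float = 19 / 214
    admin_horizon_days: float = 1460.0  # ~4-year study window
    dropout_rate: float = 1 / 730.0  # non-administrative censoring, per day
    p_male: float = 144 / 214
    p_ever_smoker: float = 148 / 214
    p_ps_2_4: float = 5 / 214
    p_gene_abnormal: float = 63 / 214  # EGFR mutation or ALK rearrangement
    p_operation: float = 0.25
    p_radiation: float = 0.30
    histology_p: dict = field(default_factory=lambda: dict(_DEFAULT_HISTOLOGY))
    stage_p: dict = field(default_factory=lambda: dict(_DEFAULT_STAGE))
    gs_category_p: dict = field(default_factory=lambda: dict(_DEFAULT_GS_CATS))
    age_mean: float = 66.0
    age_sd: float = 11.0
    age_range: tuple = (25, 85)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("cohort size must be >= 2")
        probs = [self.p_ild, self.p_male, self.p_ever_smoker, self.p_ps_2_4,
                 self.p_gene_abnormal, self.p_operation, self.p_radiation,
                 self.target_event_fraction]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        for name, dist in (("histology_p", self.histology_p),
                           ("stage_p", self.stage_p),
                           ("gs_category_p", self.gs_category_p)):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")
        if self.target_event_fraction > 0 and self.baseline_hazard is None:
            if self.p_ild == 0 and self.beta_hfs != 0:
                pass  # still feasible: events at baseline hazard alone
        if self.target_event_fraction > 0 and self.admin_horizon_days <= 0:
            raise ValidationError("events requested but the follow-up horizon is 0")


@dataclass(frozen=True)
class ReaderNoiseSpec:
    """Between-reader disagreement model for region-level reads.

    ``extent_scale=None`` means "calibrate the 5%-grid noise kernel to the
    realised cohort so the population ICC of reader HFS equals ``target_icc``".
    Readers never report fibrosis in a region whose true read is fully normal,
    so patients without ILD are scored identically by all readers.
    """

    n_readers: int = 2
    extent_scale: float | None = None  # SD of the noise kernel, in 5% steps
    target_icc: float = 0.96
    category_confusion: float = 0.0  # P(reticular read as reticular + traction)
    laa_sd: float = 0.0  # Gaussian jitter on LAA percentages

    def __post_init__(self) -> None:
        if self.n_readers < 1:
            raise ValidationError("need at least one reader")
        if not 0 < self.target_icc <= 1:
            raise ValidationError("target ICC must lie in (0, 1]")


# ---------------------------------------------------------------------------
# HFS excess distribution on the reader lattice


def _lattice_round(x: np.ndarray) -> np.ndarray:
    """Round positive excesses to the nearest lattice point, never to zero."""
    v = np.round(x / LATTICE_STEP) * LATTICE_STEP
    return np.maximum(v, LATTICE_STEP)


def _excess_lattice_pmf(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the lattice-rounded truncated-exponential HFS excess."""
    m, b = spec.hfs_excess_mean, spec.hfs_excess_max
    z = 1.0 - np.exp(-b / m)

    def cdf(x):
        return np.clip((1.0 - np.exp(-np.clip(x, 0, b) / m)) / z, 0.0, 1.0)

    k_max = int(round(b / LATTICE_STEP))
    pts = np.arange(1, k_max + 1) * LATTICE_STEP
    upper = pts + LATTICE_STEP / 2
    lower = pts - LATTICE_STEP / 2
    lower[0] = 0.0  # sub-half-step draws are bumped up to one lattice step
    upper[-1] = b
    pmf = cdf(upper) - cdf(lower)
    return pts, pmf / pmf.sum()


def _sample_excess(spec: CohortSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from the truncated exponential, lattice-rounded."""
    m, b = spec.hfs_excess_mean, spec.hfs_excess_max
    u = rng.random(size)
    x = -m * np.log1p(-u * (1.0 - np.exp(-b / m)))
    return _lattice_round(x)


# ---------------------------------------------------------------------------
# Baseline-hazard calibration


def _event_probability(lam: float, x: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """P(event observed | HFS excess x) under exponential event and censoring."""
    rate = lam * np.exp(spec.beta_hfs * x)
    total = rate + spec.dropout_rate
    return rate / total * (1.0 - np.exp(-total * spec.admin_horizon_days))


def calibrate_baseline_hazard(spec: CohortSpec) -> float:
    """Solve for the baseline hazard that hits the target event fraction.

    The expected event fraction mixes patients without ILD (excess 0, weight
    ``1 - p_ild``) with the exact lattice distribution of positive excesses;
    the root is found with Brent's method on the log hazard.
    """
    if spec.baseline_hazard is not None:
        return spec.baseline_hazard
    pts, pmf = _excess_lattice_pmf(spec)

    def expected_fraction(log_lam: float) -> float:
        lam = np.exp(log_lam)
        p0 = _event_probability(lam, np.zeros(1), spec)[0]
        p1 = float(np.sum(pmf * _event_probability(lam, pts, spec)))
        return (1.0 - spec.p_ild) * p0 + spec.p_ild * p1

    target = spec.target_event_fraction
    if target <= 0:
        return 0.0
    lo, hi = np.log(1e-12), np.log(1.0)
    if expected_fraction(hi) < target:
        raise ValidationError("target event fraction unreachable under this censoring")
    return float(np.exp(brentq(lambda g: expected_fraction(g) - target, lo, hi, xtol=1e-12)))


# ---------------------------------------------------------------------------
# Cohort simulation


def _categorical(rng, p: dict, size: int) -> np.ndarray:
    labels = list(p.keys())
    return rng.choice(labels, size=size, p=[p[k] for k in labels])


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table: scores, covariates and follow-up per patient.

    Returns a DataFrame in the cohort CSV schema (one row per patient) with
    columns ``patient_id, hfs, gs, age, sex, ecog_ps, smoking, histology,
    stage, gene_abnormality, operation, radiation, time_days, event,
    censor_reason``. Deterministic given ``(spec, seed)``.
    """
    spec = spec or CohortSpec()
    master = np.random.SeedSequence(seed)
    rng_scores, rng_cov, rng_surv = (np.random.default_rng(s) for s in master.spawn(3))
    n = spec.n

    # HFS: mixture of exactly-100 and lattice-rounded truncated-exponential excess
    ild = rng_scores.random(n) < spec.p_ild
    excess = np.zeros(n)
    excess[ild] = _sample_excess(spec, int(ild.sum()), rng_scores)
    hfs = 100.0 + excess

    # GS: severity category, then an integer score within the category band
    gs_cat = _categorical(rng_scores, spec.gs_category_p, n)
    gs = np.array([
        rng_scores.integers(_GS_BANDS[c][0], _GS_BANDS[c][1] + 1) for c in gs_cat
    ], dtype=float)

    age = np.clip(np.round(rng_cov.normal(spec.age_mean, spec.age_sd, n)),
                  *spec.age_range).astype(int)
    sex = np.where(rng_cov.random(n) < spec.p_male, "male", "female")
    smoking = np.where(rng_cov.random(n) < spec.p_ever_smoker, "ever", "never")
    ecog = np.where(rng_cov.random(n) < spec.p_ps_2_4, "2-4", "0-1")
    histology = _categorical(rng_cov, spec.histology_p, n)
    stage = _categorical(rng_cov, spec.stage_p, n)
    gene = rng_cov.random(n) < spec.p_gene_abnormal
    operation = rng_cov.random(n) < spec.p_operation
    radiation = rng_cov.random(n) < spec.p_radiation

    # event and censoring times
    lam0 = calibrate_baseline_hazard(spec)
    rate = lam0 * np.exp(spec.beta_hfs * excess)
    t_event = np.where(rate > 0, rng_surv.exponential(1.0, n) / np.where(rate > 0, rate, 1.0), np.inf)
    t_drop = rng_surv.exponential(1.0 / spec.dropout_rate, n) if spec.dropout_rate > 0 else np.full(n, np.inf)
    t_admin = spec.admin_horizon_days
    time = np.minimum(np.minimum(t_event, t_drop), t_admin)
    time = np.maximum(time, 0.5)  # diagnosis dates have day resolution; floor at half a day
    event = (t_event <= t_drop) & (t_event <= t_admin)
    reason = np.full(n, "none", dtype=object)
    dropped = ~event & (t_drop < t_admin)
    reason[dropped] = rng_surv.choice(_DROPOUT_REASONS, size=int(dropped.sum()), p=_DROPOUT_REASON_P)
    reason[~event & ~dropped] = "admin_end"

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "hfs": hfs,
            "gs": gs,
            "age": age,
            "sex": sex,
            "ecog_ps": ecog,
            "smoking": smoking,
            "histology": histology,
            "stage": stage,
            "gene_abnormality": gene,
            "operation": operation,
            "radiation": radiation,
            "time_days": np.round(time, 1),
            "event": event,
            "censor_reason": reason,
        }
    )


# ---------------------------------------------------------------------------
# Region-level reads


def _distribute_steps(total_steps: int, order: tuple, max_per_region: int = 20) -> dict:
    """Spread ``total_steps`` 5%-steps over six regions, remainder zone-first."""
    if not 0 <= total_steps <= 6 * max_per_region:
        raise ValidationError(f"{total_steps} extent steps not representable in six regions")
    q, rem = divmod(total_steps, 6)
    alloc = {r: q for r in order}
    for r in order[:rem]:
        alloc[r] += 1
    return alloc


def _true_region_steps(hfs_target: float, patient_id: str) -> dict:
    """Reticular 5%-steps per region reproducing the target HFS exactly."""
    total = (hfs_target - 100.0) * 6.0 / 5.0  # reader mean -> total steps
    if abs(total - round(total)) > 1e-6 or total < 0:
        raise ValidationError(
            f"patient {patient_id}: HFS {hfs_target} is not reachable on the"
            " six-region 5% grid"
        )
    return _distribute_steps(int(round(total)), _BASAL_FIRST)


def _kernel(scale: float, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Gaussian-weight noise kernel on [lo, hi] steps, renormalised."""
    ks = np.arange(max(lo, -12), min(hi, 12) + 1)
    w = np.exp(-(ks.astype(float) ** 2) / (2.0 * scale**2))
    return ks, w / w.sum()


def _noise_moments(r_steps: int, scale: float) -> tuple[float, float]:
    """Mean and variance (in points) of the truncated noise for one region."""
    if r_steps == 0 or scale <= 0:
        return 0.0, 0.0
    ks, p = _kernel(scale, -r_steps, 20 - r_steps)
    mean = float(np.sum(p * 5.0 * ks))
    var = float(np.sum(p * (5.0 * ks) ** 2) - mean**2)
    return mean, var


def _population_icc(cohort_steps: list, scale: float) -> float:
    """Exact population ICC of two iid noisy readers for a realised cohort."""
    mu, v = [], []
    for alloc in cohort_steps:
        moments = [_noise_moments(r, scale) for r in alloc.values()]
        mu.append(sum(r for r in alloc.values()) * 5.0 / 6.0 + sum(m for m, _ in moments) / 6.0)
        v.append(sum(w for _, w in moments) / 36.0)
    var_between = float(np.var(mu, ddof=1))
    mean_within = float(np.mean(v))
    if var_between == 0:
        return 1.0 if mean_within == 0 else 0.0
    return var_between / (var_between + mean_within)


def calibrate_noise_scale(cohort: pd.DataFrame, target_icc: float) -> float:
    """Noise-kernel scale whose exact population ICC equals the target.

    Enumerates the truncated discrete kernel per patient, so boundary effects
    (regions that cannot be read below 0% or above 100%) are accounted for
    exactly rather than approximated with a Gaussian closed form.
    """
    steps = [_true_region_steps(h, p) for h, p in zip(cohort["hfs"], cohort["patient_id"])]
    if _population_icc(steps, 12.0) > target_icc:
        raise ValidationError(
            f"target ICC {target_icc} unreachable: even the widest kernel"
            " leaves the cohort more concordant"
        )
    return float(brentq(lambda s: _population_icc(steps, s) - target_icc, 1e-3, 12.0, xtol=1e-10))


_LAA_REPRESENTATIVE = {0: 0.0, 1: 15.0, 2: 40.0, 3: 65.0, 4: 85.0}


def simulate_reads(
    cohort: pd.DataFrame,
    noise: ReaderNoiseSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit per-reader six-region reads consistent with each patient's scores.

    Fibrosis: the patient's target HFS is decomposed exactly into reticular
    extents on the 5% grid (basal-predominant), then each reader perturbs each
    involved region by a discrete noise kernel. Emphysema: the target GS is
    decomposed into six 0-4 band scores (apical-predominant) mapped to
    representative LAA percentages. With zero noise, scoring the reads
    reproduces every patient's HFS and GS exactly.

    Returns a DataFrame in the region-read CSV schema: one row per
    patient x reader x region.
    """
    noise = noise or ReaderNoiseSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = noise.extent_scale
    if scale is None:
        scale = calibrate_noise_scale(cohort, noise.target_icc) if noise.target_icc < 1 else 0.0

    rows = []
    for _, pat in cohort.iterrows():
        alloc = _true_region_steps(float(pat["hfs"]), str(pat["patient_id"]))
        gs_total = int(round(float(pat["gs"])))
        if not 0 <= gs_total <= 24:
            raise ValidationError(f"patient {pat['patient_id']}: GS {pat['gs']} outside [0, 24]")
        gs_alloc = _distribute_steps(gs_total, _APICAL_FIRST, max_per_region=4)
        for reader in range(1, noise.n_readers + 1):
            for region in REGION_IDS:
                r = alloc[region]
                if r > 0 and scale > 0:
                    ks, p = _kernel(scale, -r, 20 - r)
                    r = r + int(rng.choice(ks, p=p))
                reticular_pct = 5.0 * r
                as_traction = (
                    r > 0
                    and noise.category_confusion > 0
                    and rng.random() < noise.category_confusion
                )
                laa = _LAA_REPRESENTATIVE[gs_alloc[region]]
                if noise.laa_sd > 0:
                    laa = float(np.clip(laa + rng.normal(0.0, noise.laa_sd), 0.0, 100.0))
                rows.append(
                    {
                        "patient_id": pat["patient_id"],
                        "reader_id": f"R{reader}",
                        "region_id": region,
                        "pct_normal": 100.0 - reticular_pct,
                        "pct_reticular": 0.0 if as_traction else reticular_pct,
                        "pct_reticular_tb": reticular_pct if as_traction else 0.0,
                        "pct_honeycomb": 0.0,
                        "laa_percent": laa,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Direct variance-components ratings (for agreement-estimator checks)


def simulate_ratings(
    n: int,
    icc: float,
    k: int = 2,
    subject_sd: float = 10.0,
    subject_mean: float = 105.0,
    rater_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Gaussian two-way ratings with a known population ICC.

    Ratings are ``mu + subject_i + rater_j + noise_ij`` with the residual
    variance set so that sigma_s^2 / (sigma_s^2 + sigma_r^2 + sigma_e^2)
    equals ``icc`` - the population value that ICC(2,1) estimates.
    """
    if not 0 < icc <= 1:
        raise ValidationError("population ICC must lie in (0, 1]")
    total_noise = subject_sd**2 * (1.0 - icc) / icc
    err_var = total_noise - rater_sd**2
    if err_var < 0:
        raise ValidationError("rater variance alone already exceeds the noise budget")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, size=(n, 1))
    rater = rng.normal(0.0, rater_sd, size=(1, k))
    eps = rng.normal(0.0, np.sqrt(err_var), size=(n, k))
    return subject_mean + subj + rater + eps
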