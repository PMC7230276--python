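# Methods

## Scoring model

The HRCT fibrosis score treats each of six lung regions (three axial levels
× two lungs) as a partition of regional lung area into four finding
categories with fixed weights: normal 1, reticular 2, reticular with
traction bronchiectasis 3, honeycombing 4. Extents are read in 5% steps and
must sum to 100% per region, so a region score `sum(weight * extent%)` lies
in [100, 400] and is linear in the extents. A reader's HFS is the arithmetic
mean of the six region scores; the patient HFS is the mean over readers.
Averaging happens at the reader level (final reader HFS/GS), not on raw
region reads — this matches how two independent readers' results are
conventionally combined and keeps a single reader's internal consistency
intact.

Consequences of the grid worth knowing:

* a single reader's HFS moves in steps of 5/6 of a point (one 5% step in one
  region changes the six-region mean by 5·Δweight/6), so not every printed
  integer score is exactly grid-reachable;
* severity bands are implemented half-open — none (= 100), mild (100, 200],
  moderate (200, 300], severe (300, 400] — because reader-averaged scores
  are non-integer (e.g. 122.5) while the band definitions are printed as
  integer ranges. A patient at 104 is mild, consistent with the worked
  examples.

The Goddard score maps each region's low-attenuation-area percentage to a
band score via contiguous half-open intervals ≤5% → 0, (5, 25] → 1,
(25, 50] → 2, (50, 75] → 3, > 75 → 4. The printed band definitions leave
gaps (e.g. 5–6%); the half-open convention is the unique contiguous,
order-preserving completion that agrees with all printed interior values.
Band scores are summed over the six regions (0–24) and averaged over
readers; severity: none (= 0), mild (0, 7], moderate (7, 15], severe
(15, 24].

Validation rejects off-grid extents by default; an explicit opt-in snaps to
the nearest 5% step with ties resolved away from the normal category (a
reader on the fence about an abnormality is taken to have seen one), with
the residual absorbed by the normal extent.

Ground-glass opacity and organised post-treatment lesions are not score
categories; readers are expected to fold such area into the partition before
input. Any subset of one or more readers is accepted; the patient score
averages whoever read the patient.

For risk analysis, patients are stratified at 100 and 110 HFS points
(no ILD / minimal fibrosis / more than two 5%-regions-worth of excess),
with ordinal scores 0, 1, 2. The trend statistic is invariant to affine
rescaling of these scores, so any equal spacing is equivalent.

## Agreement

Inter-observer agreement uses the intraclass correlation. Because the two
pulmonologist readers are treated as interchangeable raters from a
population of raters and absolute agreement (not just consistency) is the
question, the default form is ICC(2,1):

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with MSR/MSC/MSE the subject/rater/residual mean squares of the two-way
ANOVA without replication. ICC(3,1) (two-way mixed, consistency) is
available where the specific raters are the only raters of interest.
F-based confidence intervals (Shrout–Fleiss; Satterthwaite df for the
ICC(2,1) case) are computed only on request. A matrix with no
between-subject variance yields a defined non-positive estimate with a
warning rather than an error.

## Prevalence and the 2×2 comparison

Proportions are reported in percent with the Wald interval
p̂ ± z·√(p̂(1−p̂)/n) (z = 1.959964 at 95%), deliberately unclipped — near-zero
prevalences conventionally print negative lower bounds. The Wilson score
interval is available as an alternative. The ILD / pneumonitis association
is tested with the Pearson chi-square on the 2×2 table via the closed form
N(ad−bc)²/∏(margins), Yates correction optional (off by default; both
variants are far below 0.0001 on the motivating table).

## Time-to-event analysis

* **Kaplan–Meier**: product-limit estimator over distinct event times;
  right-continuous, non-increasing, identically 1 under complete censoring.
* **Trend log-rank**: with per-subject ordinal scores s, the statistic is
  U²/V ~ χ²(1), where U sums observed-minus-expected scores over event times
  and V is the hypergeometric variance (terms with one subject at risk are
  skipped). With two groups scored 0/1 this is exactly the two-sample
  log-rank test; p-values are two-sided.
* **Cox proportional hazards**: Newton–Raphson on the partial likelihood
  with analytic gradient and observed information, Breslow tie handling by
  default (matching the convention of the commercial packages this pipeline
  mirrors) and Efron behind a flag. Covariates are centred and scaled
  internally for conditioning and the estimates transformed back.
  Convergence: max |score| < 1e-9 or step < 1e-10, at most 50 iterations,
  with step halving. Monotone likelihoods (complete separation of risk
  sets) are detected by a runaway standardised coefficient or collapsed
  information; the estimate is capped and flagged non-converged rather than
  reported as a finite MLE. Singular information raises. SEs come from the
  inverse observed information; CIs are Wald intervals exponentiated to the
  hazard-ratio scale.
* **Replaced-multiple analysis**: the primary covariate (HFS − 100) is
  refitted alongside each adjuster in its own bivariable model and the
  primary coefficient reported from every model — a stability analysis,
  deliberately not a full multivariable model (at ~19 events a ten-covariate
  model would be badly overfitted). Factor levels with zero events are
  flagged "n/c" and excluded from that factor's model instead of silently
  dropped.

Censoring (death, hospital transfer, loss to follow-up, switch to immune
checkpoint inhibitors, administrative end) is treated as non-informative
right-censoring; no competing-risks model is fitted. Time origin is the
first anti-cancer drug administration, in days; only a patient's first
pneumonitis event counts.

## Synthetic-data generator

The generator emulates the cohort structure the analysis assumes; defaults
are the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n` | 214 | cohort size |
| `p_ild` | 61/214 | P(HFS > 100) |
| `hfs_excess_mean` | 15 points | mean of the truncated-exponential HFS excess |
| `hfs_excess_max` | 100 points | truncation bound (all synthetic ILD is mild) |
| `beta_hfs` | log 1.16 | true log hazard ratio per HFS point |
| `target_event_fraction` | 19/214 | expected pneumonitis fraction |
| `admin_horizon_days` | 1460 | administrative follow-up window (~4 y) |
| `dropout_rate` | 1/730 per day | non-administrative censoring hazard |

Covariate marginals (sex, smoking, performance status, histology, stage,
gene abnormality, GS category) follow the cohort characteristics table;
operation (0.25) and radiation (0.30) are plausible values chosen once since
no marginals are reported for them. Covariates are drawn independently — the
joint distribution is unreported — so the no-confounding limit is exact in
the generator, which is precisely what the replaced-multiple stability
property assumes. Event times are exponential with hazard
λ₀·exp(β·(HFS−100)); **λ₀ is not a guess** but is solved by Brent
root-finding so that the expected observed-event fraction under the exact
lattice distribution of HFS and the censoring model equals the target. HFS
excesses are drawn by inverse-CDF from the truncated exponential and rounded
to the 5/6-point reader lattice (never to zero, preserving `p_ild`).

Region reads are reconstructed from each patient's scores: the HFS excess is
decomposed exactly into per-region reticular 5%-steps with the remainder
placed basally (fibrosis is basal-predominant); GS is decomposed into
per-region band scores with the remainder placed apically. With zero reader
noise, scoring the reads reproduces every patient's HFS and GS exactly.

Reader noise is a discrete kernel on the 5% grid (Gaussian weights,
support ±12 steps, truncated to each region's feasible range). Readers never
report fibrosis in a truly normal region, so HFS = 100 patients are read
identically by everyone — radiologically, readers do not hallucinate
reticulation in normal lungs. Because 71.5% of patients sit on the HFS = 100
boundary, Gaussian variance-components algebra misstates the achievable
agreement; the calibration therefore computes the population ICC
(between-patient variance of the expected reader score over total variance)
**exactly, by enumerating the truncated kernel per patient**, and solves for
the kernel scale hitting the target ICC (default 0.96) for the realised
cohort. A separate plain Gaussian ratings generator with closed-form
variance components exists for exercising the ICC estimator in isolation.

What the generator does *not* emulate: correlated covariates, time-varying
hazards or non-proportional effects, informative censoring, competing
mortality risk, reader category confusion beyond an optional
reticular→traction flag, and moderate/severe ILD (absent from the motivating
cohort). Passing tests on synthetic data therefore demonstrate the
correctness of the arithmetic and estimators under the stated model, not
robustness to these real-data features.

## Numerical and testing choices

Simulation sizes were chosen to keep the full suite fast while leaving
Monte-Carlo error well below the tolerances tested: 500 replicate cohorts
for Cox parameter recovery, 200 for ICC recovery, 20 000-patient single
draws for marginal checks. Cross-checks against independent implementations
(statsmodels `PHReg` for Cox at 1e-6, lifelines for Kaplan–Meier and
log-rank, pingouin for ICC) are tests only; the implementations here are
self-contained.

## Known limitations

* The Cox partial-likelihood MLE carries a first-order small-sample bias at
  the default study scale (~19 events per cohort of 214): the mean estimated
  per-point HR over many replicates sits ≈ 0.005 above the generating value
  of 1.16. This is a property of the estimator, not of the implementation
  (reference implementations produce identical estimates on identical data),
  and it vanishes by n ≈ 2000.
* Printed confidence intervals in small published tables are often rounded
  inconsistently with any single method; the Wald choice here reproduces the
  motivating prevalence interval to ≤ 0.1 percentage point but CI bounds
  should not be expected to match third-party output digit for digit.
* The HFS excess distribution (truncated exponential, mean 15) is a
  modelling choice constrained only by the ILD fraction and the requirement
  that all three risk strata be populated; real HFS distributions may be
  shaped differently.
* ICC confidence intervals for ICC(2,1) use the Satterthwaite approximation
  and degrade for very small n or ICC near 1.
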