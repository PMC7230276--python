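# hfscore

Semi-quantitative HRCT scoring of pre-existing interstitial lung disease
(ILD) and emphysema in lung-cancer patients, with the downstream
time-to-event analysis of anti-cancer drug-induced pneumonitis risk.

Pre-existing ILD — even mild fibrosis without honeycombing — predisposes
lung-cancer patients to drug-induced pneumonitis, but guideline pattern
classification largely ignores mild disease. This package implements a
quantitative alternative for biostatisticians and pulmonology researchers:

* **HRCT fibrosis score (HFS).** Six lung regions (right/left lung at the
  carina, at the right inferior pulmonary vein, and midway between) are each
  read as a partition into four findings with weights *w* — normal (1),
  reticular abnormality (2), reticular + traction bronchiectasis (3),
  honeycombing (4) — in 5% extent steps. The region score is
  `sum(w_c * extent_c%)`, the reader HFS is the six-region mean, and the
  patient HFS averages readers. 100 = normal lungs; 400 = complete
  honeycombing. Bands: none (=100), mild (100, 200], moderate (200, 300],
  severe (300, 400].
* **Goddard score (GS).** Per-region low-attenuation-area percentage mapped
  to a 0–4 band score, summed over the six regions (0–24) and averaged over
  readers.
* **Risk pipeline.** Inter-observer agreement via ICC(2,1) computed from the
  two-way ANOVA mean squares; prevalence with Wald/Wilson intervals; Pearson
  2×2 chi-square; Kaplan–Meier product-limit curves; the trend log-rank test
  across the ordered strata HFS = 100, (100, 110], > 110; and Cox
  proportional-hazards models (Newton–Raphson on the partial likelihood,
  Breslow or Efron ties), including the one-at-a-time bivariable
  ("replaced multiple") sensitivity analysis of the HFS effect.
* **Synthetic cohorts.** A generator that reproduces the structure such a
  study assumes — ~28.5% mild ILD, covariate marginals of a chemotherapy
  cohort, an event hazard log-linear in (HFS − 100) calibrated to a ~9%
  event fraction, administrative plus dropout censoring, and two-reader
  region-level reads with discrete 5%-grid noise calibrated to a target
  population ICC — so every analysis component is testable end to end.

## Worked example

The package's two demonstration patients (library API):

```python
>>> import hfscore as h
>>> read = h.RegionRead("ipv_L", {h.FibrosisCategory.NORMAL: 95.0,
...                               h.FibrosisCategory.RETICULAR: 5.0})
>>> h.region_points(read)          # (95 x 1) + (5 x 2)
105.0
>>> h.patient_hfs([105.0, 103.0])  # two readers' HFS, averaged
104.0
>>> h.ild_severity(104.0), h.hfs_stratum(104.0)
('mild', 'gt100_le110')
>>> h.patient_gs([18.0, 15.0]), h.emphysema_severity(16.5)
(16.5, 'severe')
```

A full synthetic analysis from the shell:

```sh
$ hfscore simulate --seed 7 --out cohort.csv --reads reads.csv
$ hfscore score --reads reads.csv --out scores.csv
$ hfscore agree --reads reads.csv --measure hfs
HFS icc2 ICC = 0.954 (n=214, k=2)
$ hfscore analyze prevalence --cohort cohort.csv
Pre-existing ILD                 59/214    27.6   21.6–33.6
Drug-induced pneumonitis         21/214     9.8    5.8–13.8
Pneumonitis | ILD                 19/59    32.2   20.3–44.1
Pneumonitis | no ILD              2/155     1.3    -0.5–3.1
Chi-square (pneumonitis by ILD)           46.14  p < 0.0001
$ hfscore analyze km --cohort cohort.csv
trend log-rank chi2(1) = 89.440, p = 3.16e-21
```

The ICC of 0.954 estimates the generator's target reader agreement of 0.96;
27.6% of this cohort draw has mild ILD; pneumonitis is concentrated in the
ILD group (32.2% vs 1.3%), and the incidence rises monotonically across the
three HFS strata. The simple-Cox table (`hfscore analyze survival`) for this
seed estimates an HFS hazard ratio of 1.20 per point (95% CI 1.15–1.26,
p < 0.0001; the generating value is 1.16), stable across all ten bivariable
adjustments. `hfscore report` renders every table and figure into a
directory with a hash manifest for byte-level reproducibility.

## Layout

| module | contents |
| --- | --- |
| `hfscore.scoring` | domain types, HFS/GS arithmetic, severity bands, strata |
| `hfscore.agreement` | ICC(2,1)/ICC(3,1) with optional F-based CIs |
| `hfscore.cohort_stats` | proportion CIs, 2×2 chi-square |
| `hfscore.survival` | Kaplan–Meier, trend log-rank, Cox (Breslow/Efron), replaced-multiple |
| `hfscore.synthetic` | cohort/reads/ratings generators with deterministic calibration |
| `hfscore.io`, `hfscore.report`, `hfscore.cli` | CSV schemas, tables/figures, `hfscore` CLI |

See `docs/methods.md` for the statistical methods, the generator's
assumptions, and known limitations.
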