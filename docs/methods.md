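# Methods

This note records the statistical model, its parameters, the synthetic
registry generator's design and limits, and the numerical choices made in
the implementation. Problem sizes quoted here (registry sizes, replicate
counts) are this package's own defaults, chosen so the full test suite
runs in minutes on one CPU.

## 1. Data model

A registry is four tables:

- `patients(patient_id, sex, age_at_first_symptoms, age_at_start)`
- `prescriptions(prescription_id, patient_id, drug, treatment_line,
  start_date, end_date, baseline_edss)` — one per patient-drug episode;
  `end_date` empty while treatment continues
- `visits(prescription_id, month, edss, new_t2_count, gd_count)` — annual
  examinations at months 0, 12, …, 60; lesion counts may be missing
- `relapses(prescription_id, month_of_onset, edss_increase)`

`read_registry` enforces a parse contract (month grid, EDSS on the 0.5
grid, unique `(prescription, month)`); `validate_registry` checks all
structural rules (keys, domains, date order, month-0 visit equal to the
baseline EDSS, non-negative lesion counts) and returns a violation report
rather than raising, so a pipeline can fail with an actionable listing.

## 2. Follow-up truncation and panels

Follow-up for a prescription is the maximal contiguous run of annual
visits 0, 12, 24, …: one missing year ends the window and later visits
are discarded, because a gap breaks both the relapse-ascertainment and
the confirmation logic. A recorded `end_date` additionally caps the
window at the number of whole calendar months of exposure.

Within the observed window, relapse onsets determine the panel:

- `R0` — no relapse;
- `R1` — exactly one onset in the closed interval [6, 15] months;
- `R2` — exactly one onset in (15, 27] months (open below so a month-15
  onset is counted exactly once, in `R1`);
- anything else is unclassified and excluded.

`R1` splits into `R1+`/`R1−` at a relapse EDSS increase of 1.0
(configurable). `R0+MRI0` is the `R0` subset with no new-T2 or
gadolinium-enhancing lesion at any in-window post-baseline visit;
prescriptions with missing lesion counts are dropped from that subset
(with a logged warning), not assumed inactive.

The `R2` panel's month-12 row reports the relapse-free (`R0`) evaluation
set flagged `pre_relapse=True`: before their second-year relapse these
prescriptions are indistinguishable from `R0`, and the duplicate flag
lets downstream models exclude the mirrored observations so no evaluation
is counted twice.

Confirmed worsening compares each annual EDSS to the *fixed* treatment
baseline: an increase of ≥ 1.5 when the baseline is < 1.0, ≥ 1.0 for
baselines in [1.0, 6.0), and ≥ 0.5 for baselines ≥ 6.0. Worsening in a
relapse panel is RAW, in `R0` PIRA, in `R0+MRI0` PIRMA.

## 3. Estimation

For one panel the per-evaluation response (worsened or not) is modelled
by a binomial GLM with logit link:

```
worse ~ C(month) [+ baseline_edss + age + C(sex)]
```

- Months at which the response is constant are dropped (their log-odds is
  not estimable; keeping them would separate the fit); at least two
  informative months are required.
- Candidate covariates (`baseline_edss`, `age`, `sex`) are kept when their
  Wald chi-squared term test in the full model has p < 0.05; constant
  columns are excluded up front since they are collinear with the
  intercept.
- **Overdispersion**: the Pearson dispersion χ²/df is computed for every
  fit. If it exceeds 1.5 the coefficient covariance is scaled by the
  dispersion (quasi-binomial); point estimates are unchanged by
  construction, standard errors inflate by a common √dispersion factor.
- **Adjusted means**: design rows are built at a fixed covariate profile
  (EDSS 2, age 30, female — approximately the cohort median) for each
  month level; the linear predictor's covariance is `L V Lᵀ`, the
  probability-scale SE follows by the delta method
  `se_p = p(1−p)·se_η`, and 95 % limits are Wald on the logit scale.
  With no covariates these adjusted means reduce *exactly* to the raw
  proportions with textbook binomial SE `√(p(1−p)/n)` — a tested
  identity.
- **Multiplicity**: all pairwise month contrasts are tested jointly. The
  single-step adjusted p-value of contrast k is
  `1 − P(max_j |Z_j| ≤ |z_k|)` under the multivariate normal with the
  contrast family's correlation matrix (Tukey-style; exact correlation,
  not the equal-n shortcut). Months are then grouped into a compact
  letter display by insert-and-absorb. A Bonferroni fallback is
  available.
- **Between-panel contrasts** (`compare_panels`) use a cell-means model
  `worse ~ C(cell) − 1` over `(arm, month)` cells, default family:
  `R1` vs `R0` at every shared month plus the lagged comparisons
  `R2@m` vs `R1@(m−12)` (each one year after its panel's relapse).
  Degenerate cells are skipped with a warning; a single-contrast family
  is reported unadjusted.

## 4. Synthetic registry generator

The generator (`generate_registry`) is fully vectorized and deterministic
given a seed. Per patient it draws:

- sex (70 % female), age at start (normal, mean 36.5, sd 9), symptom lead
  time (log-normal), baseline EDSS (categorical on the 0.5 grid, median 2);
- drug (INF 50 %, GLA 25 %, FTY 15 %, NAT 10 %) with treatment line tied
  to the drug;
- visit attendance by a chain of annual retention probabilities
  (0.90, 0.55, 0.47, 0.40, 0.45) — strong early attrition as in
  real-world registries; dropouts get an `end_date`;
- at most one relapse per treatment year with hazards
  (0.10, 0.05, 0.03, 0.02, 0.02), severity high with probability 0.58
  (EDSS increase 1.0–2.0) else 0.5;
- *silent progression*: a latent time at which the patient's EDSS crosses
  their confirmation threshold, with cumulative probabilities
  (0.033, 0.046, 0.050, 0.056, 0.061) at months 12–60. By construction
  the relapse-free panel's expected worsening frequency equals these
  values — this is what the coverage tests exploit;
- relapse deficit: with probability 0.27 the relapse's EDSS elevation is
  still present at the next annual visit and then decays geometrically
  (factor 0.5 per year, rounded to the 0.5 grid). The persistence value
  makes the first-annual-visit RAW frequency in the relapse panel land
  near 15 %, the realistic order of magnitude, and produces the
  characteristic *decline* of RAW at later visits (remission), opposite
  in shape to the slowly rising PIRA curve;
- MRI activity per visit by drug-specific base rates (0.08–0.32) decaying
  over treatment years, elevated to 0.42 at the visit after a relapse.

**Realism and limits.** The generator reproduces the qualitative
structure a panel analysis needs — attrition, relapse timing, remission,
silent progression independent of relapses, drug-dependent MRI activity —
but it is not a disease model: EDSS trajectories are threshold-crossing
events rather than random walks, relapses are capped at one per year,
covariates do not influence progression (so covariate selection on
synthetic data should, correctly, keep nothing), and calendar effects,
drug switches and within-patient correlation across prescriptions are
absent. Defaults are the package's study conditions; every test runs
against them unchanged.

`make_fixture_from_counts` solves the inverse problem at desk scale: given
published per-`(arm, month)` evaluation and worsening counts it emits a
deterministic registry whose panel table reproduces those counts exactly
(with consistency checks: `R1±` must partition `R1`, `R0+MRI0` must nest
in `R0`, an `R2` month-12 row must mirror `R0`).

## 5. Numerical choices

- **CSV round-trips are exact.** Floats are written with `%.17g` and read
  back with Python's `float()` per element (the C parser underlying
  `pandas.to_numeric` can be off by the last ulp); lesion counts use the
  nullable `Int64` dtype so missing scans are representable. A written
  registry reads back bit-identical, which makes pipeline runs
  reproducible across serialization.
- **Multivariate-normal rectangle probabilities** for single-step p-values
  use `scipy.stats.multivariate_normal.cdf` with a fixed generator
  (deterministic), `allow_singular=True` (contrast families are rank
  deficient by construction), `maxpts=50 000` and `abseps=1e-4`. The
  resulting p-value noise (~3·10⁻⁴) is far below what a 0.05 decision
  needs, and caps the cost of a 10-contrast family below a second.
- **Separation guard**: fits with a coefficient magnitude above 30 on the
  logit scale are rejected as separated rather than reported with
  meaningless standard errors.
- Dates are compared in whole calendar months (year/month arithmetic with
  a day-of-month correction), never by dividing day counts by 30.44.

## 6. Problem sizes

| Quantity | Default | Where |
|---|---|---|
| Study-scale simulation | 6 000 patients | `default_config()` |
| Coverage study | 200 registries × 2 500 patients | acceptance tests |
| Type-I-error study | 200 registries × 2 000 patients | acceptance tests |
| Invariant property sweep | 100 registries × 300 patients | acceptance tests |
| Shape checks | 20 registries × 3 000 patients, pooled | acceptance tests |

The full test suite runs in roughly two minutes on one CPU; the
`scripts/acceptance.py` pipeline in well under one.
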