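# Methods

## The score

The Simplified Mobility Score combines walking speed *v* (m/s) and daily
step count (DSC, steps/day) with equal weight:

```
ws_points  = 50 · min(v / 1.35, 1)
dsc_points = 50 · min(DSC / 10000, 1)
SMoS       = ws_points + dsc_points
```

The caps (1.35 m/s, 10,000 steps/day) mark the thresholds above which the
literature associates walking speed with complete functional independence
and step count with an "active" lifestyle; above them extra performance
carries no additional score. Published descriptions of the scoring rule list
only the strict `< cap` and `> cap` branches; this package uses
`min(·, 1)`, the unique continuous reading, which assigns exactly 50 points
at the cap (both branches agree there in the limit). Scores are kept at full
precision internally; reports display one decimal place.

A patient with only one metric is never given a partial total: the component
scorers are callable individually for exploratory work, but `compute_smos`
refuses a missing metric with an error naming the absent field.

**Walking speed from a timed walk** is distance/duration; a course length
outside the standard self-selected set {30, 60, 120, 200 m} triggers a
warning, not an error. Only single walks are handled — averaging repeated
bouts is left to the caller.

**Daily step count from a time series** is the arithmetic mean over the most
recent `window_days` (default 30, "the last month") *dated entries*. Days
with no entry are excluded rather than imputed as zero, because non-wear
days carry no activity information and zero-imputation would bias the score
downward. Windows covering fewer than `min_coverage_days` (default 7) days
are flagged and warned as low coverage but still scored. The score formula
is applied to the mean DSC, not per-day and then averaged.

## Normative comparison

The bundled reference table gives the expected population SMoS mean (and a
printed dispersion) for 18 strata: {total, 30–39, 40–49, 50–59, 60–69, 70+}
× {combined, male, female}. Age bands are closed integer ranges
([30, 39], …, [70, ∞)); band inclusivity is not stated in the source table,
and the closed-range reading is the natural one for integer ages. Patients
under 30 are scored normally but have no normative band: comparison returns
an explicit lookup miss, never a silent substitution. Sexes other than
male/female are scored but skipped in sex-specific comparison, with a
warning.

The dispersion column of the reference table is stored verbatim and **never
used inferentially**. Its total rows (e.g. 3.63) are far smaller than the
subgroup values (e.g. 9.75) and are not reconstructible as pooled SDs, so no
pooled quantity is ever derived from it.

**One-sample z-test.** Each stratum's mean is compared with its population
value using only the sample standard error, treating the population mean as
a known constant:

```
z = (x̄ − μ₀) / (s/√n),   p = 2·(1 − Φ(|z|)),
CI = (x̄ − μ₀) ± z_{1−α/2} · s/√n
```

This CI construction is confirmed by the published total-row interval, whose
half-width equals 1.96 × the sample SE. Strata with n < 10 carry a small-n
flag (the smallest published stratum is n = 6); n < 2 is an error; a
zero-variance stratum is resolved by the sign of the difference and flagged.
Several of the published per-stratum P cells (and one difference cell in
each of two rows, off by 0.1 from the subtraction of their own printed
means) are not reproducible from the printed summaries under any standard z
formula; the package follows the stated formulas rather than the printed
cells.

**Two-sample (operative) contrast.** Unpooled (Welch-style) SE with normal
quantiles:

```
SE_diff = √(s₁²/n₁ + s₂²/n₂)
```

On the published group summaries (operative 50.2 ± 21.25 SD, n = 38;
non-operative 62.1 ± 22.97 SD, n = 144) this yields |difference| = 11.9,
p ≈ 0.0025. The exact CI printed for that contrast in the source analysis
(−19.88 to −4.018) is not recoverable from the printed summaries under
pooled or unpooled normal formulas; this package documents and tests its own
stated formula instead.

**Correlations.** Pearson product-moment r between SMoS and each disability
score (ODI, NDI 0–100; VAS 0–10), with pairwise deletion (so the n may
differ per score), r², and a two-sided p from the t-transform of r
(`scipy.stats.pearsonr`). Fewer than 3 complete pairs, or zero variance, is
an error rather than a NaN.

**Normality.** Shapiro–Wilk (3 ≤ n ≤ 5000) is attached to the report as a
diagnostic; it never gates any computation.

**Multiplicity.** No correction across the 18 strata by default, matching
the reference analysis; a Bonferroni-adjusted column is available behind a
flag. α defaults to 0.05 two-sided, configurable.

## Cohort I/O

The cohort CSV schema is
`patient_id,age,sex,walking_speed_mps,walk_distance_m,walk_time_s,daily_step_count,odi,ndi,vas,operative`.
Rows failing validation (non-numeric fields, age < 18, disability scores out
of range, negative gait values, unparseable operative flags) are returned as
row-numbered issues, never silently dropped; rows_in = records_out +
issues_out always holds. When both a direct speed and a timed walk are
present the direct speed wins with a note. Sex accepts {M, F, male, female}
case-insensitively; the operative flag accepts {0, 1, true, false, yes, no}
(an absent column means all non-operative, with a warning). Only the age
exclusion is enforced by the reader; walking-aid use is not a schema field.
JSON reports carry full precision with a stable key order; text reports
round scores to 1 dp, r to 3 dp, and display p below 0.001 as "< .001".

## Synthetic cohorts

The generator emulates the statistical structure of a spine-clinic cohort:

* **Latent totals.** Per (age band × sex) stratum, SMoS totals are drawn
  from N(mean, sd) truncated to [0, 100] by rejection sampling. A spec whose
  truncation would discard more than half the normal mass is rejected as
  infeasible rather than silently distorted. With the cohort-level SDs
  implied by the published standard errors (≈ 17–24 points), truncation is
  *not* negligible: the realised mean of a stratum specified as
  N(58.7, 22.7) is ≈ 57.2. Recovery checks therefore compare sample means
  with the analytic truncated-normal expectation
  (`truncated_normal_moments`), which is what the generator actually
  targets.
* **Operative shift.** Flags are Bernoulli(operative_fraction); the shift is
  added to operative patients' latent mean before truncation. When stratum
  means describe a cohort that already contains its operative patients (the
  study-emulation spec), `center_operative_shift=True` splits the shift as
  +shift·(1−f) / −shift·f so the stratum marginal mean is preserved while
  the between-group gap equals the shift.
* **Component split.** The published analyses do not constrain the joint
  WS/DSC distribution, so a total S is split uniformly over the feasible
  interval [max(0, S−50), min(50, S)] — the maximally non-informative
  choice — and the scoring formulas are inverted on their sub-cap branches
  (speed = points·1.35/50, steps = points·10000/50), so re-scoring the
  emitted raw metrics reproduces the latent points to ~1e−14.
* **Disability scores.** A Gaussian copula on one pooled SMoS axis
  (standardised by the realised cohort moments, since disability tracks
  absolute mobility, not stratum-relative mobility):
  `z_d = ρ·z_smos + √(1−ρ²)·ε`, score = scale·Φ(z_d + c). The offset
  c = √2·Φ⁻¹(target_mean/scale) places the marginal mean (defaults ODI 40,
  NDI 26, VAS 7, the validation cohort's reported means). The monotone Φ
  mapping attenuates Pearson correlation by a known factor
  (cov(z, Φ(z+c)) = φ(c/√2)/√2 over the mapped SD, = √(3/π) ≈ 0.977 at
  c = 0), so the latent ρ is the target r divided by that factor and the
  delivered SMoS–score correlation lands on the target (residual bias
  ≈ 0.01, well inside the ±0.05 recovery band at n = 2000).
* **Defaults** reflect the validation-study conditions: operative fraction
  38/182, shift −11.9 points, correlation targets −0.570 (ODI), −0.561
  (VAS), −0.037 (NDI). Ages are uniform integers within the band (70+ is
  sampled as 70–89, matching the study's observed maximum of 88). The step
  time-series generator uses a truncated normal with a fixed default end
  date (2020-06-30) so output is byte-reproducible from the seed alone.

**What the generator does not emulate:** real joint structure between
walking speed and step count, within-day step patterns, device measurement
error, non-normal score distributions, or missingness mechanisms. Passing
recovery tests therefore show that the pipeline's arithmetic is correct
under the stated model, not that real cohorts satisfy the model.

## Problem sizes in the test suite

Monte-Carlo checks use 200 seeds × 2000 records for parameter recovery,
1000 replicates for the two-sample difference coverage and Shapiro–Wilk
calibration (n = 200 under the null, n = 500 for the skew power check), and
12 seeds at the published per-stratum sizes for the effect-pattern
reproduction; the full suite runs in a few seconds.

## Known limitations

* The score is population-calibrated: both caps come from high-income,
  device-owning populations, and the bundled norms inherit that bias. Caps
  and norms are replaceable (config / `--norms`), and any non-default cap is
  recorded in report metadata.
* The one-sample test treats the population mean as exact; uncertainty in
  the normative values themselves is not propagated.
* Device accuracy (step-detection and GPS-based speed error) is out of
  scope; inputs are taken at face value.
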