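# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `kdecho`.

## The normative model and Z-score classification

The reference model is fitted on day-0 (pre-treatment) measurements only.
In the default **regression** mode, the measurement is regressed by
ordinary least squares on √BSA, where BSA = k·W^(2/3) (Meeh's allometric
formula; k = 9.8 cm²·g^(−2/3) for mice, overridable). The residual SD uses
the n−2 denominator, so on the training baseline the standardized
residuals satisfy Σz = 0, Σz² = n−2 and sd(z, ddof=1) = √((n−2)/(n−1))
exactly — closed forms the test suite asserts to 1e−9. In the degenerate
**mean_sd** mode the intercept is the sample mean, the slope 0, and the
scale the (n−1)-denominator sample SD; this mode is appropriate when the
baseline carries no usable body-size spread (and is what a plain
"mean ± SD" reference range corresponds to). Which mode a given published
reference range used is generally not recoverable from the range itself,
so both are first-class and neither is asserted to be "the" original
computation.

Z-scores are computed on raw millimetres by default — body size enters
through the √BSA regressor, and adjusting the response by weight as well
would double-count size. Weight-adjusted inputs remain possible for
sensitivity analyses, since any column can be scored.

Classification is strict: a coronary artery lesion (CAL) is flagged iff
Z > 3.0. Z exactly 3.0 is normal. The per-animal false-positive rate under
the model is Φ(−3) = 0.00135.

The choice of BSA formula only rescales the regressor: any positive
monotone transform of weight yields the same fitted values at the same
weights, so the Meeh constant does not affect Z-scores in either mode
beyond the regression's leverage structure.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes:

- **Design.** Dose groups control/low/medium/high (nominal 0/1/2/4 mg/kg —
  labels only; the literature on this model states doses sparsely, so
  effects are configured explicitly per group rather than derived from a
  dose–effect law), 9 animals per group followed at days 0, 7, 14, 21, 28;
  plus a stand-alone day-0 normative cohort (default N = 38). Whether a
  published "n = 9 per time point" means per group or in total is
  ambiguous; the default is 9 per group per day and both are configurable.
- **Weights.** Baseline 20.0 ± 1.5 g with linear growth 0.15 g/day and
  0.2 g day-level noise — a plausible trajectory for 4–5-week-old male
  C57BL/6 mice (~20 g).
- **Norms.** Day-0 coronary inner 0.217 ± 0.028 mm and outer
  0.472 ± 0.056 mm are the anchored reference ranges; carotid, aortic,
  wall and ejection-fraction norms are free parameters with defaults
  chosen to be anatomically plausible for this animal (carotid
  0.45/0.60 mm inner/outer, aorta 1.05/1.20 mm, walls 0.075 mm, EF 65 %).
- **Effects** are additive mean shifts in units of the measurement's
  normative SD, per (group, day, measurement). Coronary inner: high
  +2 SD at day 7 rising to +5 SD at days 21–28; medium +1 → +3; low
  +0.5 → +1.5; control identically 0. Walls thicken early (up to +3 SD
  carotid, +2 SD aortic in the high group), outer diameters dilate, and
  the high-dose ejection fraction drops 1.5 SD at day 21. Expressing
  effects in SD units makes every classification rate analytically
  checkable: with the medium-dose coronary shift of +3 SD the mean sits
  exactly at the cutoff, so P(Z > 3) = 1/2; with the high-dose +5 SD
  shift and the 0.04 mm absolute measurement noise used for dilated
  coronaries, P(Z > 3) = Φ((5·0.028 − 3·0.028)/0.04) = Φ(1.4) ≈ 0.919.
- **Noise.** Post-baseline noise is the normative SD times a global
  scale, except where an absolute SD override applies (default: 0.04 mm
  for the coronary inner diameter in the medium/high groups, reflecting
  the larger caliper error on a dilated, irregular vessel).
- **Severity coupling.** Each animal carries a latent standard-normal
  severity factor. In treated groups after day 0 it loads (ρ = 0.6) on
  the coronary inner diameter and on the whole carotid vessel (walls,
  inner diameter and annulus). This yields population correlations of
  ρ² = 0.36 between carotid wall and coronary diameter and ≈ 0.43
  between carotid outer diameter and coronary diameter — a reproducible
  analogue of the carotid–coronary association. Loading the whole vessel
  rather than the outer diameter alone is deliberate: it models dilation
  as a vessel-level response and is what makes the outer-diameter
  correlation strong while preserving the outer ≥ inner constraint.
- **Outer diameters** are generated as inner + max(gap, 0), with the
  annulus gap's mean and SD derived from the configured norms
  (μ_gap = μ_outer − μ_inner, σ_gap = √(σ_outer² − σ_inner²)). At day 0
  and in controls both marginals then match the configured normative
  mean/SD (the gap truncation at 0 affects < 10⁻³ of aortic rows and
  ~10⁻⁷ of coronary rows), and outer ≥ inner holds in every record by
  construction rather than by rejection. In treated groups the coupling
  inflates the carotid outer marginal SD slightly (~0.056 vs 0.05
  configured); exact-marginal guarantees are therefore stated only for
  the pure normative (day-0/control) distribution.
- **Missingness** is per-measurement Bernoulli (default 0), and the
  baseline cohort supports per-measurement sample-size caps
  (`baseline_ns`, e.g. 18 of 38 animals contributing the coronary inner
  diameter and 37 the outer), emulating incomplete measurability.
- **Determinism.** One `numpy` Generator seeded from the config; the
  order of draws is fixed, so identical config + seed gives a
  byte-identical CSV.

What the generator does **not** emulate: repeated-measures correlation
beyond the severity factor (within-animal residuals are independent
across days), non-Gaussian tails, operator drift, heteroscedasticity in
body size, or any pharmacokinetics. Passing tests therefore demonstrate
the correctness and calibration of the analysis pipeline under its own
assumptions, not the biology of real LCWE cohorts.

## Cohort statistics

Group × day cells are summarized as n, mean and SEM (= sd/√n; missing for
single-value cells, and empty cells are absent rather than zero).
Contrasts use the pooled-variance two-tailed Student's t (df = n₁+n₂−2),
with Welch's form behind a flag. Associations use Pearson's r with the
t-transform p-value (df = n−2); the carotid↔coronary pairs are evaluated
on weight-adjusted values at day 28 by default, with raw mm available. No
multiple-testing correction is applied, matching common practice in this
literature; the analysis report states the number of tests performed.
Missing values are dropped cellwise/pairwise, never imputed. The
dose-response table orders group means by dose rank and flags per-day
monotonicity; under null effects with two groups the flag is a fair coin,
which the suite verifies.

## Calibration experiments and problem sizes

`kdecho.experiments` (used by `scripts/acceptance.py` and the calibration
tests) measures, from full pipeline runs:

- recovery of the day-0 coronary reference statistics from 200
  independent baseline cohorts at the study's per-measurement sample
  sizes (n = 18 inner, n = 37 outer) — the mean of per-cohort sample SDs
  is expected slightly below σ (E[s] = c₄(18)·σ ≈ 0.0276 for
  σ = 0.028), well within the stated ±0.003 check;
- the control-group percent Z > 3 at days 21/28 (9 animals per day,
  100 seeds) — median 0 %, with ≥ 95 % of seeds exactly 0 %;
- high- and medium-dose day-28 classification rates at n = 10,000
  simulated animals against the analytic Φ(1.4) ≈ 91.9 % and 50 %;
- the null rate P(Z > 3) = 0.00135 on 100,000 normative draws.

These classification checks score against a reference model fitted on a
large (n = 20,000) day-0 normative sample. That choice is deliberate: the
analytic rates above assume the population parameters, and a model fitted
on an n ≈ 38 baseline adds ~4–11 percentage points of seed-to-seed spread
to the measured rates (3σ̂-threshold noise of order 3σ/√(2n) plus mean
noise σ/√n, amplified through the normal density). The large-sample fit
isolates the property under test — the calibration of the Z > 3 rule —
from baseline sampling noise, which is instead exercised by the
study-scale fitting tests. All experiment sizes are chosen so the whole
calibration suite runs in seconds.

## Numerical and degenerate-input choices

- Regression fitting refuses < 3 values, zero √BSA variance (with a
  message pointing to `mean_sd`), and zero residual SD; `mean_sd` refuses
  < 2 values and zero SD.
- `percent_above` ignores missing Z-values and errors when all are
  missing; scoring a missing observation yields a missing result, never a
  silent zero.
- The cutoff comparison is strict (`>`), so boundary values never flag.
- Generator clips: lengths at 10⁻⁶ mm, ejection fraction to (0.5, 100],
  annulus gaps at 0, body weight at 1 g — all far in the tails under any
  realistic configuration.
- CSV round trips rely on the shortest-round-trip float repr, so
  read(write(x)) is exact; model JSON round trips are bit-exact.
- Zero-SD ("zero-noise") configurations are allowed as the degenerate
  limit of the generator and produce the configured means exactly; model
  fitting on such data errors rather than standardizing by zero.

## Known limitations

- The generator's independence of within-animal residuals across days
  understates longitudinal autocorrelation; mixed-effects or
  repeated-measures modelling is out of scope (the analysis mirrors
  t-test/Pearson practice).
- The normative model assumes a single homoscedastic residual SD; no
  LMS/percentile-curve or variance modelling.
- Real-cohort p-values and effect magnitudes (e.g. the exact
  ejection-fraction drop) are not reproducible from synthetic data;
  direction and calibration are what the suite verifies.
- The carotid outer marginal SD is approximate (not exact) in treated
  groups, as described above.
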