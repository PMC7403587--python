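# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Study design being modeled

A cohort of telemetered rats is recorded for several baseline days, then
subjected to 3 consecutive days of 8-h forced activity in a slowly rotating
wheel, either during the rest phase (rest work, RW; zeitgeber time ZT2–10,
lights on at ZT0 in a 12:12 light–dark cycle) or during the active phase
(active work, AW; ZT14–22). Vigilance states are scored in 10-s epochs
(wake W, NREM sleep N, REM sleep R); per-epoch EEG 1–4 Hz power (SWA) and
EMG peak-to-peak amplitude accompany the hypnogram; core temperature is
stored at 10-s resolution. After the third shift, spatial memory (Morris
Water Maze latency), serum corticosterone and prefrontal-cortex protein
markers (p-eIF4E, p-BMAL1, p-S6K1, Arc) are measured once per animal.

## Hypnogram metrics

* **Bouts** are maximal runs of one state with at least `min_run` epochs
  (default 3, i.e. ≥ 30 s, for NREM bouts). Shorter runs are discarded
  entirely; runs are never merged across interruptions.
* **Latencies** are reported to the first epoch of the first qualifying run
  (onset convention): REM latency = 3 consecutive REM epochs; stable-sleep
  latency = 6 consecutive epochs of sleep, where "sleep" is {NREM, REM}
  combined. Latencies are anchored at the end of the second work shift
  (after the third shift not all animals reach REM before tissue
  collection); a recording that ends before a qualifying run yields a
  censored (missing) latency, which is excluded from group means and
  dropped listwise in regressions, with the count logged.
* **Binned state times** use bins aligned to ZT0 of the first recording day.
  Partial bins — leading or trailing — are dropped so every reported bin
  covers exactly the bin width (2 h by default).
* **Quiet wakefulness (QW)** is the set of wake epochs whose EMG
  peak-to-peak amplitude is ≤ the 33rd percentile of EMG over all wake
  epochs of the analyzed segment (ties included). The percentile uses
  linear interpolation between order statistics (`numpy.percentile`
  default); the estimator is configurable because the convention is not
  uniquely determined by the ≤-33rd-percentile rule alone. The threshold is
  computed per animal per analyzed segment (baseline and work segments
  separately), which scopes "all wakefulness values" to the data actually
  summarized.

## SWA, artifact rejection, normalization, SWE

* **SWA** is the band-integrated EEG power in 1–4 Hz (inclusive on both
  edges) from an unwindowed FFT per 10-s epoch at 250 Hz; with the one-sided
  power-spectrum scaling used, the values over all bins sum to the epoch's
  mean squared amplitude. Units are arbitrary but consistent; every
  downstream use is a ratio, rank or within-animal accumulation, so the
  scale convention never matters. No taper is applied by default (the
  signals are analyzed unfiltered); a taper hook can be added by filtering
  the signal before calling the routine.
* **Artifact rejection** flags epochs whose SWA exceeds the segment mean by
  5 sample SDs, computed in a single pass per animal per segment
  (non-iterative). A constant segment (SD 0) produces no flags. The manual,
  visual component of artifact screening in a live laboratory is out of
  scope.
* **Baseline normalization** divides each epoch's SWA by the animal's
  baseline mean SWA for the same vigilance state in the same circadian 2-h
  bin. The 2-h granularity matches the reporting granularity of the rest of
  the analysis; a missing (state, bin) reference cell raises an error that
  names the cell rather than silently imputing.
* **SWE** per 2-h ZT-aligned bin is (number of qualifying epochs) × (their
  mean SWA), which is algebraically the sum of SWA over those epochs; the
  cumulative trajectory is its running sum. Artifact epochs are excluded
  from both factors. SWE is computed on raw SWA by default with a
  `swa=` override for baseline-normalized values, since either convention
  is defensible and the group contrasts are invariant to the choice within
  animal.

## Temperature processing and cosinor

* **Artifact filter**: consecutive non-overlapping 100-sample blocks; a
  sample is masked when it deviates from the block mean by more than 2 °C
  *or* more than 5 block SDs (OR is the conservative exclusion). Block
  statistics include the candidate sample and are computed once (single
  pass). Samples are masked, never deleted. A sliding-centered window is
  available for sensitivity analysis.
* **Normalization** subtracts the mean over the 4-day baseline window
  (baseline average set to 0); the operation is idempotent.
* **Binning** averages valid samples into 5-min bins; empty bins stay
  missing and are simply omitted from the cosinor design (no imputation).
* **Cosinor**: least squares of `M + A·cos(2π(t − φ)/τ)` at fixed τ = 24 h
  via linearization on cos/sin regressors; `A = √(β_c² + β_s²) ≥ 0` by
  construction and φ = atan2(β_s, β_c) mapped to [0, 24). Fits use 72-h
  spans (the last 72 baseline hours; the 3 work days). On noiseless cosine
  input recovery is exact to 1e-6; 5-min bin averaging attenuates a 24-h
  cosine by a sinc factor of ≈ 2×10⁻⁵, negligible at the precision
  reported. Multi-component cosinor, confidence ellipses and
  zero-amplitude tests are out of scope (the design is entrained, the
  period known). **Amplitude change** = work amplitude − baseline
  amplitude; negative means damping.
* The baseline-normalization window (4 days) and the fit span (72 h) are
  independent parameters rather than forced to coincide.

## Group statistics

Unpaired comparisons use the pooled-variance Student *t* with
df = n₁ + n₂ − 2 (a Welch option exists behind a flag but is not the study
convention); both raw-vector and (mean, sd, n) summary entry points are
provided and agree exactly. Cohen's *d* for independent groups uses the
root-mean-square of the two group SDs,
`d = (m₂ − m₁)/√((s₁² + s₂²)/2)`; this convention — rather than the
df-weighted pooled SD — is the one that reproduces the worked effect size
from the printed group summaries (0.72 vs 0.77 for the pooled-SD variant),
so it is the default and the validated choice. For paired data the
statistic is `t = mean(diff)/(sd(diff)/√n)` with df = n − 1; because the
paired effect-size convention cannot be identified from printed values,
both candidates are reported (`d` = mean(diff)/sd(diff) and `d_rms` with
the RMS of the condition SDs) and neither is asserted against external
numbers. Effect-size labels use the conventional 0.2 / 0.5 / 0.8
boundaries, inclusive. No multiple-testing correction is applied (α = 0.05
throughout, matching the analysis convention; the family-wise behavior is a
documented property, not corrected away).

## Hierarchical regression ledger

Step *k* regresses an outcome on the union of predictor blocks 1..k by OLS
(statsmodels under the hood). Each step reports R², adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1) (negative values allowed and
meaningful), the change in adjusted R² versus the previous step, and the
*cumulative model's* overall F with (p, n − p − 1) df — the convention the
target tables use — with a block-increment partial-F available behind a
flag. Missing data are deleted listwise per outcome, so outcomes can have
different n. Rank-deficient designs raise an error naming the dependent
columns; duplicate variables across blocks are rejected at the later step.
Small samples (residual df ≤ 5) trigger a warning rather than an error,
because the design intentionally runs 4 blocks (6 predictors) on cohorts of
9–13 in the worst case. Predictors are not standardized by default (R² and
its derivatives are scale-invariant).

The default block order is: (1) work condition; (2) daily rhythm dynamics —
temperature-amplitude change and REM latency; (3) sleep drive — mean NREM
bout length and quiet-wake SWE; (4) serum corticosterone (protein outcomes
only). For spatial memory the sleep-drive markers come from the last 24 h of
the work period; for the protein outcomes they come from the 2-h window
between the end of the third shift and tissue collection, because protein
phosphorylation reflects minute-to-hour-scale biology. Step-3 variants
substitute NREM SWE or cumulative NREM+REM sleep to test specificity.

## Synthetic-telemetry generator

The generator produces data *with the statistical structure the analysis
assumes*; it makes no mechanistic claim.

* **Hypnograms** follow a per-epoch Markov chain over {W, N, R}, simulated
  run-by-run (geometric sojourns, memoryless truncation at segment
  boundaries — distributionally identical to the per-epoch chain but ~50×
  faster). Transition rates are segment-specific: the sleep→wake exit rate
  is solved from a two-state stationary balance so each segment's wake
  fraction hits its target exactly. Targets: 72.9% wake in the dark phase
  and 71.6% sleep in the light phase at baseline (the nocturnality the
  study reports). REM is entered only from NREM. During shifts the state is
  forced to wake except micro-sleep epochs (NREM) at probability 0.02 per
  epoch. After a shift the chain enters a **rebound** regime — wake-fraction
  targets of 0.38 (RW) / 0.45 (AW) — so sleep redistributes into off-work
  hours and total daily sleep stays comparable between conditions (~600–630
  min/day on work days), the design's key null. A geometric **wind-down**
  period of sustained wakefulness (mean 12 min RW, 30 min AW) precedes
  rebound sleep; it sets the sleep-onset and REM latencies and their
  right-skewed spread. Rest workers additionally get a ×2 NREM→REM rate
  boost for 3 h post-shift (REM rebound), which shortens their REM latency
  by roughly 40–50 min relative to active workers.
* **Between-animal heterogeneity** ("shift-work tolerance"): per-animal
  jitter on wake-fraction targets (SD 0.03), lognormal scales on wake-run
  lengths (σ 0.15) and REM-entry rate (σ 0.20), a lognormal scale on all
  SWA gains (σ 0.2), and Gaussian per-animal baseline amplitude
  (SD 0.10 °C) and damping (SD 0.15 °C). These produce the overlapping
  group distributions the individual-differences analysis needs; without
  them every group contrast would be unrealistically clean.
* **Features**: a latent sleep-pressure process S rises exponentially toward
  1 in wake (τ = 8 h), decays toward 0.05 in NREM (τ = 2.2 h) and holds in
  REM; SWA = state gain × S × lognormal noise with gains ordered
  NREM (200) > quiet wake (80) > active wake (30) ≳ REM (25). Wake EMG is a
  two-component lognormal mixture with a low-tone component of weight 1/3
  (what the 33rd-percentile rule recovers). Rest workers get a ×1.5 SWA
  gain on quiet-wake epochs during work days — the planted
  degraded-waking-state effect, sized so the cumulative QW-SWE contrast
  lands at d ≈ 1–1.5 while NREM SWE stays null.
* **Temperature**: mesor 37.2 °C + 24-h cosine (acrophase ZT18) + a
  5-min-smoothed wake increment (0.03 °C) + Gaussian noise (SD 0.15 °C).
  The cosine amplitude is set to the target *fitted* amplitude (0.64 °C)
  minus the analytic first-harmonic contribution of the wake increment, so
  the cosinor estimate lands on target. On work days the amplitude is
  reduced by the condition's damping (−0.40 °C RW, −0.09 °C AW — the AW
  value sized to a near-threshold paired effect). Artifact spikes of
  5–10 °C are injected at rate 10⁻³ per sample (configurable).
* **Outcomes** are drawn from declared linear models over the *measured*
  per-animal predictors (the generator consumes the analysis products, so
  the planted block structure is exactly what the ledger should recover),
  standardized by fixed nominal constants rather than sample statistics to
  keep each animal independent of cohort composition. Corticosterone
  carries the collection-time structure (RW sampled at ZT12 sits above AW
  at ZT0). Coefficients are sized so that, at the default cohort (17 RW /
  13 AW), the spatial-memory ledger reproduces the qualitative target
  pattern — sleep-drive gain > rhythm gain > 0 — in ≳ 85% of replicate
  cohorts, p-S6K1 is dominated by work condition (R² ≈ 0.85, flat
  thereafter), p-eIF4E gains most from the corticosterone step, and Arc is
  predicted by nothing beyond a weak condition effect. MWM latency is
  clipped to the task's [5, 120] s range.
* **Determinism**: every animal draws from streams keyed by
  (seed, animal index, stream), so regeneration is bit-identical and
  growing the cohort never perturbs existing animals.

What the generator does **not** emulate: raw EEG/EMG waveforms (epoch-level
features only; raw-signal synthesis exists solely to unit-test the band-power
routine), mechanistic thermoregulation, scorer disagreement or scoring
drift, EEG artifact epochs (only temperature artifacts are injected), and
any within-animal day-to-day adaptation across shifts. Passing tests
therefore demonstrate that the *analysis* is correct and well-calibrated on
data with the assumed structure — not that real telemetry satisfies those
assumptions.

## Problem sizes and numerical choices

Replicate-based checks use deliberately chosen sizes: 1000 random
hypnograms for the bout oracle, 500 replicates for ledger power at n = 13,
200 for null-block calibration, 100 pooled simulated days (50 animals × 2
days, which keeps between-animal trait variance in the pooled estimate
below 0.5 percentage points) for the wake-fraction calibration, and 15–25
replicate full cohorts for the ledger-pattern rate. Acrophase grid search
(the cosinor oracle) uses a 0.01-h grid. Ties in the QW threshold are
included by the ≤ comparison; percentile interpolation is linear. The
Markov-chain relaxation after the light–dark transition leaves a small
(~0.4 percentage point) systematic deficit in the pooled dark-phase wake
fraction relative to the stationary target; it is a property of any
finite-relaxation chain and is documented rather than compensated.

## Known limitations

* The hypnogram chain is memoryless within segments; real sleep shows
  longer-tailed bout distributions and homeostatic coupling between
  consecutive bouts.
* The quiet-wake threshold is scoped per analyzed segment; a per-animal,
  all-days scope is equally defensible and exposed via the API.
* The paired effect-size convention is intentionally left dual (see group
  statistics); consumers must pick one explicitly.
* With 6 predictors on n ≈ 9–13, ledger steps can reach 1–3 residual df;
  the package warns but proceeds, because reproducing that regime is part
  of the design. Interpret such steps qualitatively.
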