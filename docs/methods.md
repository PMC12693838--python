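# Methods

This note documents the models, numerical choices and limitations behind
`resthrv`, in the order the pipeline runs.

## IBI preprocessing

**Clock convention.** All timestamps are milliseconds on a fixed local
clock (0 = local midnight); a `BeatSeries` carries a `clock_offset_ms`
mapping recording time to clock time. All intervals are half-open
`[start, end)`, and a beat falling exactly on a segment boundary belongs to
the later segment. No time-zone arithmetic is attempted.

**Night window and segmentation.** Nocturnal smartwatch recordings are
restricted to [12am, 5am) and tiled with 5-minute (300,000 ms) segments —
60 per night. The first beat inside the window carries no IBI (its
predecessor lies outside), so windowing never fabricates an interval.
Morning chest-strap recordings (2–5 min) bypass the window and are treated
as a single segment of the full recording length; VLF is not computed for
them (below).

**Completeness.** A segment's completeness is the fraction of its duration
covered by plausible IBIs: the sum of IBI annotations of beats inside the
segment, divided by 300,000 ms and capped at 1. IBIs above the absolute
physiological bound (2000 ms) are gap-spanning intervals from missing
beats and are *not* counted as coverage — crediting them would let a
segment with a long dropout pass the coverage rule. The keep threshold is
**inclusive**: completeness ≥ 0.70 is kept. Both the threshold and the
definition are config-exposed, since "70% complete" admits a
beat-count-based reading as well; coverage time was chosen because it is
invariant to heart-rate differences between people.

**Movement exclusion.** Any segment overlapping a minute with a positive
step count is invalidated (`movement`), however small the count — motion
corrupts pulse detection long before it registers many steps. Minutes with
no step record follow a configurable policy (default: keep, with a logged
warning).

**Spurious-IBI filter.** Two rules: an absolute range ([300, 2000] ms) and
a relative rule flagging IBIs deviating more than 25% from the centred
running 5-beat median. Both thresholds are configuration parameters. The
filter iterates to a fixed point — removing an artifact sharpens the local
median for its neighbours, so a single pass is not idempotent, while the
fixed point is by construction. A beat whose predecessor was removed keeps
its timestamp but loses its IBI annotation (set to NaN): the interval it
described no longer exists, and recomputing it across the gap would
manufacture a long artificial IBI. A segment in which more than half the
beats are rejected is invalidated as an `artifact_burst` rather than
trusted. Validity accounting is exact: kept + low-completeness + movement
+ artifact-burst counts always sum to the segment total.

**Interpolation.** Surviving IBI annotations are resampled to a uniform
tachogram by a cubic spline of IBI versus beat time, evaluated at
`seg_len × rate` sample times (default 4 Hz → 1200 samples per 5-minute
segment). Outside the span of observed beats the edge value is held
(cubic extrapolation overshoots). With fewer than four annotated beats the
spline falls back to linear; fewer than two is an error. 4 Hz comfortably
covers the 0.40 Hz upper HF bound.

## HRV metrics

RMSSD and SDNN are computed on the cleaned IBI annotations of each segment
(not on the tachogram): RMSSD = √(mean of squared successive differences),
SDNN = sample standard deviation with the n−1 denominator. Both match an
independent brute-force implementation to 1e−9 in the test suite.

Band powers integrate a Welch periodogram of the mean-removed tachogram:
Hann windows of up to 512 samples with 50% overlap and per-window linear
detrend, `scaling="density"`, integrated over half-open bands. Defaults
are the conventional VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz, all
overridable. Integrated total power approximates the tachogram variance
(Parseval); the test suite verifies 5% agreement on deterministic
multi-band signals, where the check is exact up to leakage — for a single
stochastic segment the periodogram's own sampling variability (several
percent at 300 s) dominates, which is a property of the data, not the
estimator. VLF is omitted, with a warning, for recordings shorter than
300 s: the band's lowest period does not fit in the recording, and
five minutes is the accepted minimum for frequency-domain HRV.

Per-night records are the unweighted mean of each metric across valid
segments (a pooled-beats alternative exists behind the `aggregation`
config flag; the segment-mean default weights each 5-minute epoch equally
rather than each beat). Log transforms are natural-log, stored alongside
the raw value, and skipped (with a log entry) for non-positive values.

## Two-level correlation model

The estimator of record is a bivariate two-level random-intercept model,

    (x_ij, y_ij) = μ_i + b_i + w_ij,   b_i ~ N(0, Σ_b),   w_ij ~ N(0, Σ_w),

fit by maximum likelihood. Each 2×2 covariance is parametrized as
(log sd_x, log sd_y, atanh r), which enforces positive-definiteness and
puts the correlation on an unconstrained scale. Sufficient statistics —
person means, the pooled within-person scatter matrix, and person groups
by cluster size — are precomputed, so one likelihood evaluation is O(#
distinct cluster sizes); the between-level mean (intercept plus optional
person-level covariates) is profiled out by exact GLS at every evaluation.
Optimization is L-BFGS-B with box bounds (log-sd ∈ [−6, 3] after
standardizing both variables to unit total variance, atanh r ∈ [±7.5]);
hitting a variance bound sets a `variance_at_boundary` flag. Standard
errors come from the finite-difference Hessian of the profile negative
log-likelihood; the correlation's SE is delta-method,
se(r) = (1 − r²)·se(atanh r).

**Why latent person means.** The between-person correlation refers to the
latent b_i, not observed person averages; with n observations per person
and intraclass correlation ρ, an observed-average correlation is
attenuated by ρ·n/(ρ·n + 1 − ρ). The method-of-moments fallback
(`moments_observed`: person-centred values within, observed person means
between) is retained for transparency and labelled attenuated; the two
estimators agree within 0.02 once persons contribute ≥ 20 observations.

**Tests.** p-values are two-sided Wald tests of the correlation against
zero using its delta-method SE, referred to a t distribution with
cluster-based degrees of freedom — m − 1 − q for the between level (m
persons, q adjustment covariates) and N − m − 1 for the within level.
The t reference is the standard finite-sample correction for cluster-level
inference; with a normal reference the between-level test at m = 100 is
measurably anti-conservative (empirical type-I ≈ 6% at α = 0.05 in this
package's own calibration runs; ≈ 5.2% with the correction).

**Adjustment.** Age and gender enter as between-level regressors on the
(standardized) covariates, so the reported between-person correlation is a
partial correlation given them; the within level is untouched, matching
the fact that person-constant covariates carry no day-level information.
Constant covariates are dropped with a warning.

**Biserial correlations.** Person-level binary variables (diagnoses,
yes/no baselines) use the biserial estimator
r_b = (M₁ − M₀)/s_y · p(1−p)/φ(Φ⁻¹(p)), which estimates the correlation
with the latent continuous variable assumed to underlie the dichotomy.
Estimates outside [−1, 1] (possible in small samples) are clipped and
flagged. Its p-value uses the approximate null SE √(pq)/φ/√(n−1). Binary
variables at the within level are rejected by a guard: a person-constant
binary has no day-level variance, and day-varying binaries are out of
scope.

**ICC.** Var(BP) and Var(WP) come from a one-way random-effects model fit
by REML (statsmodels MixedLM; optimizer falls back lbfgs → bfgs → powell
on numerical failure). Negative component estimates are truncated at zero.
ICC = Var(BP)/(Var(BP) + Var(WP)). For balanced panels this REML estimate
coincides with the one-way ANOVA moment estimator, which the test suite
uses as an independent oracle.

**Lag alignment.** Health measures reported on day *t* can be paired with
HRV from the following night (or next morning), the natural causal
ordering for "does today's stress show in tonight's HRV"; `same_day` joins
are the default elsewhere. Unmatched days are dropped and counted. EMA
items administered several times a day are collapsed to daily means before
analysis.

## Synthetic-data generators

**IBI model.** IBI_k = mean_ibi + A·sin(2πf·t_k) + AR(1) noise, with the
sinusoid representing respiratory sinus arrhythmia (f defaults to 0.25 Hz,
a normal sleeping respiratory rate) and the AR(1) term (φ = 0.3) the
residual beat-to-beat variability. The sinusoid contributes successive-
difference RMS A·√2·|sin(πfT)| (T = mean IBI in s); the AR(1) term
√(2σ²(1−φ)). The noise variance is solved so the two add in quadrature to
the target RMSSD — making realized RMSSD predictable (within 10% over ≥ 1 h
under the defaults) and HF power controllable through A. A target below
what the sinusoid alone implies is an explicit parameter error. Defaults
(mean IBI 1000 ms, RMSSD 40 ms, A = 20 ms) describe a typical healthy
sleeping adult. Artifacts are injected in the classes the filter must
remove: contiguous missing-beat gaps (a configured fraction of beats),
split-beat spurious insertions (rate per 100 true beats), and movement
minutes with positive step counts in the paired step table. The generator
does **not** emulate circadian sleep architecture, device-specific noise
signatures, or PPG waveforms — so passing tests certify the pipeline's
rules and formulas, not robustness to every real-device pathology.

**Panel model.** y_ij = μ + √icc·b_i + √(1−icc)·w_ij with b rows drawn
from the between-person correlation matrix and w from the within-person
one, so configured correlations and ICCs are exactly the generating
values. Correlation matrices are validated for symmetry, unit diagonal and
positive semi-definiteness (the error names the offending eigenvalue).
Age is uniform on a configurable range (default 18–65), gender
Bernoulli(0.5); both act only at the between level via configurable
weights, on top of the unit latent variance. Binary variables are observed
once per person by thresholding the latent person-level value at the
quantile matching the configured prevalence. The truth object stores the
config and the realized latent effects, enabling exact recovery tests.

## Power simulation

Each replicate draws a fresh panel and tests the target-level correlation
with the ML estimator's Wald-t test; power is the rejection proportion
with binomial MC SE √(p̂(1−p̂)/n_reps). Replicate seeds are spawned from
the master seed via `numpy.random.SeedSequence`, so runs are reproducible
and replicates independent. Degenerate replicates are counted; more than
5% aborts the run. Defaults — 100 persons × 9 observations, ICC 0.5 for
both variables, two-sided α = 0.05, 1000 replicates, non-target level's
correlation 0 — are the package's declared reference conditions for its
sample-size results; under them, measured power is ≈ 80–82% for a
between-person r of 0.30 and ≈ 81% for a within-person r of 0.10 (the
package's own acceptance runs). With the non-target correlation set to 0,
the two claims are separable; simultaneous correlations at both levels
change power only marginally.

## Problem sizes used in the test suite

Unit tests run at seconds-scale sizes. The deeper suites use: 1000
replicate panels per power claim; 1000 null replicates per level for
type-I calibration; a 27-cell recovery grid (between r ∈ {0, .3, .5} ×
within r ∈ {−.2, 0, .1} × ICC ∈ {.55, .68, .89}) at 1000 persons × 10
days, with ICC bias averaged over 3 replicate panels per cell (a single
panel's realized ICC carries ~0.015 sampling noise, so a one-draw check
would conflate sampling error with bias). The full suite completes in
about five minutes on one CPU.

## Known limitations

- The within-level estimator assumes a common within-person covariance
  across persons and days (no autocorrelation, no heteroscedasticity);
  real diary data often violate both.
- Biserial SEs are approximate; for small samples a likelihood or
  bootstrap interval would be preferable.
- The Wald-t between-level test is accurate at m ≳ 50 persons; for very
  few clusters a likelihood-ratio or resampling test should replace it.
- Missing data are handled by pairwise day joins and person-level listwise
  deletion for covariates — correct under missing-completely-at-random,
  optimistic otherwise.
- Week-level designs are handled by reading `day_index` as a week index;
  calendar alignment between measures within a week is the caller's
  responsibility.
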