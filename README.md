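# resthrv

Analysis pipelines for **resting heart-rate variability (HRV) measured by
consumer wearables** — smartwatches, chest straps and rings that record
interbeat intervals (IBIs) night after night in people's everyday lives —
and for relating those nightly HRV metrics to daily health measures
(stress, mood, sleep quality, health behaviors) collected alongside them.

The package is aimed at researchers running intensive longitudinal /
ecological-momentary-assessment studies who need to:

1. turn raw timestamped IBI streams into clean, artifact-filtered
   resting-HRV metrics per person-night, and
2. estimate how HRV relates to health measures **at two distinct levels** —
   day-to-day fluctuations within a person, and stable differences between
   persons — which naive pooled correlations conflate.

## What it computes

**IBI preprocessing** (`ibi_pipeline`): beats are clipped to the nocturnal
clock window [12am, 5am), tiled into 5-minute segments, and a segment is
kept only if ≥ 70% of it is covered by IBIs and no steps were recorded in
any overlapping minute. Spurious IBIs (device artifacts: missed beats,
split beats) are removed by an absolute physiological range rule
([300, 2000] ms) and a running-median deviation rule (> 25% from the
centred 5-beat median), iterated to a fixed point. Surviving segments are
cubic-spline resampled to a uniform 4 Hz tachogram.

**HRV metrics** (`hrv_metrics`): RMSSD = √(mean((IBIₖ₊₁ − IBIₖ)²)) and
SDNN (sample SD of IBIs) in the time domain; Welch-periodogram band powers
VLF (0.0033–0.04 Hz), LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) in ms², and
the LF/HF ratio, in the frequency domain. VLF is suppressed for recordings
under five minutes. Segment metrics are averaged into per-person-per-night
records; natural-log transforms are available for skewed metrics.

**Two-level associations** (`multilevel_assoc`): for a variable pair
(x<sub>ij</sub>, y<sub>ij</sub>) observed on person *i*, day *j*, a
bivariate random-intercept model

    (x_ij, y_ij) = μ + b_i + w_ij,   b_i ~ N(0, Σ_b),   w_ij ~ N(0, Σ_w)

is fit by maximum likelihood. The **within-person correlation** is the
correlation in Σ_w (day-level fluctuations), the **between-person
correlation** the one in Σ_b (latent person means, free of the attenuation
that affects correlations of observed person averages). Between-person
estimates can be adjusted for age and gender (partial correlation at the
between level). Binary person-level variables use the biserial correlation.
Effect sizes follow the 0.10 / 0.30 / 0.50 small/medium/large convention.
The intraclass correlation ICC = Var(BP) / (Var(BP) + Var(WP)) is estimated
by one-way random-effects REML.

**Power simulation** (`power_sim`): Monte-Carlo power and type-I error for
the within- and between-level correlation tests in person × day designs.

**Synthetic data** (`synthetic_data`): generators with exact ground truth —
IBI series whose RMSSD and HF power are analytically controlled (a
respiratory-sinus-arrhythmia sinusoid plus AR(1) noise), with injectable
gaps, spurious beats and movement minutes; and two-level panels with
configurable between/within correlation matrices, ICCs, binary thresholds
and covariate effects.

## Worked example

```python
from resthrv import *

# one synthetic 5-hour night, target RMSSD 40 ms
rec = generate_ibi_recording(IbiGenConfig(duration=18000.0, target_rmssd=40.0, seed=11))
segs, rej = preprocess_recording(rec.series, rec.steps)
kept = [s for s in segs if s.valid == "kept"]
record = aggregate_daily([segment_metrics(s) for s in kept], "p0", 0)
print(f"segments kept: {len(kept)}/60")
print(f"nightly RMSSD: {record.rmssd:.1f} ms  SDNN: {record.sdnn:.1f} ms")

# a two-level panel: 200 persons x 9 days, known truth
cfg = PanelGenConfig(n_persons=200, n_obs_per_person=9,
                     between_corr=[[1, -0.25], [-0.25, 1]],
                     within_corr=[[1, -0.10], [-0.10, 1]],
                     icc=(0.68, 0.40), seed=3)
panel, truth = generate_panel(cfg)
est = multilevel_corr(panel, ("x", "y"), covariates=("age", "gender"))
print(f"between r = {est.between_r:+.3f} (p = {est.between_p:.3f}, {label_effect(est.between_r)})")
print(f"within  r = {est.within_r:+.3f} (p = {est.within_p:.3f}, {label_effect(est.within_r)})")
d = variance_components(panel, "x")
print(f"ICC(x) = {d.icc:.2f}  Var(BP) = {d.var_bp:.2f}  Var(WP) = {d.var_wp:.2f}")
```

Output:

```
segments kept: 60/60
nightly RMSSD: 39.9 ms  SDNN: 32.7 ms
between r = -0.186 (p = 0.015, small)
within  r = -0.090 (p = 0.000, below_small)
ICC(x) = 0.66  Var(BP) = 0.65  Var(WP) = 0.33
```

The clean night keeps all 60 five-minute segments and the realized RMSSD
(39.9 ms) matches the generator's 40 ms target. In the panel, the fitted
between-person correlation (−0.186, a "small" effect, adjusted for age and
gender) and within-person correlation (−0.090) recover the generating
−0.25 / −0.10 within sampling error at 200 persons, and the ICC of 0.66
says two-thirds of the variance in x is stable between-person difference.

A command-line interface wraps the same pipeline:

```bash
resthrv simulate --seed 5 --outdir out/
resthrv preprocess --config run.yaml --seed 5 --outdir out/
resthrv associate  --config run.yaml --seed 5 --outdir out/
resthrv icc        --config run.yaml --seed 5 --outdir out/
resthrv power --n-persons 50,100,200 --between-r 0.3 --seed 5 --outdir out/
```

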