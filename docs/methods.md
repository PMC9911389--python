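# Methods

## The data-quality metric

`erpsig` quantifies the quality of a two-condition ERP dataset as the
*percentage of significant channels*: the fraction of electrodes on which the
window-averaged potential differs between the two conditions.  The premise is
physical — volume conduction spreads any genuine cortical response across the
whole scalp, so with low enough noise a true evoked difference should be
detectable on most electrodes.  The statistic therefore rises with anything
that improves the signal-to-noise ratio of the single-trial window means and
needs no ground-truth artifact labels, which makes it usable as a benchmark
for preprocessing choices.

For one subject with condition blocks `a` and `b` (trials × channels of
window means over a fixed 100-ms window):

1. draw `n_resample = 50` trials *with replacement* from each condition;
2. per channel, run a two-sided unpaired t-test (pooled variance,
   `df = n_a + n_b − 2`) on the drawn trials' window means and mark the
   channel significant if `p < α = 0.05`;
3. record the percentage of significant channels;
4. repeat `n_boot = 20 000` times and average.

The *all-trials* variant replaces the fixed draw of 50 by each condition's
own surviving trial count, which is the right comparison when a rejection
step has changed how many trials exist.  A degenerate channel (zero variance
in both groups) is non-significant when the group means are equal (the t
statistic is taken as 0) and significant otherwise (its limit is ±∞).
Welch's test is available via `MetricConfig(welch=True)`; pooled is the
default.

### What the resampling does to the test level

Drawing `n` trials with replacement from a finite pool of `T` makes the
per-channel t-test anti-conservative: duplicated trials are treated as
independent, so the resampled group mean truly has variance
`σ²(1/n + 1/T)` while the test's denominator estimates `σ²/n`.  The t
statistic is inflated by `γ = sqrt(1 + n/T)` and the null rejection rate is
`P(|t_df| > t_crit/γ)` — about 10.9% (not 5%) for `n = 50, T = 100`,
approaching `α` only in the limit `T → ∞`.  The all-trials variant
(`n = T`) sits at `γ² = 2` (≈ 16.6%) for every pool size, which is exactly
why it is the fair variant for comparing pipelines that change `T`: its null
level does not move when trials are discarded.  None of this affects the
metric's use as a *relative* quality measure — every pipeline is scored by
the same procedure — but the metric must not be read as a calibrated test
level, and the package's analytic oracle (below) models the inflation
explicitly.

### Window selection

Following standard practice the analysis window is selected from the data:
long epochs (−1 to 2 s) are scanned in 50-ms bins stepped by 50 ms, the
per-trial value at each latency being the mean over the bin (bin means are
noise-robust and consistent with the 100-ms window logic; the alternative —
single-sample values — is noisier but would select similar windows).  The
per-subject metric at each bin is stacked across subjects; the cohort median
is smoothed with a centred 3-point moving average (the window truncates to
the valid samples at the edges) and the latency of the maximum (earliest on
ties) becomes the window centre, extended ±50 ms.  The per-latency spread is
summarised by the unscaled MAD, `median |x − median|` — descriptive only, so
no 1.4826 consistency factor is applied.  One RNG stream per subject, seeded
`seed + subject_index`, keeps per-subject curves independent of cohort
order.  A single resampling draw is shared across the latency bins of one
repetition (a draw selects whole epochs, so this mirrors evaluating the same
resample at every latency and leaves each bin's distribution unchanged).

## Comparing preprocessing methods

Two preprocessing variants are compared on their per-subject metric values
with subjects as cases: per-subject differences `d_i = a_i − b_i` are
resampled with replacement 20 000 times.  The 95% CI is the percentile
interval of the bootstrap means.  The reported p-value is the *studentized*
(bootstrap-t) one — the fraction of resamples with
`|t*| = |(mean* − mean)/se*| ≥ |mean/se|`, floored at `2/n_boot`.  The plain
two-sided percentile p-value (`2·min(P(mean* ≤ 0), P(mean* ≥ 0))`, ties in
both tails) is also reported (`p_percentile`) but not used for labelling:
on iid normal differences at paper-scale cohorts (14 subjects) it rejects
well above the nominal 5% — the percentile bootstrap of a mean is known to
be anti-conservative at small n — whereas the studentized form holds its
level there (both rates are measured in the test suite).  Since cohorts of
13–18 subjects are the realistic regime for ERP benchmarking, the
calibrated form is the default.

Reporting conventions: effects are rounded to the nearest percent; p ≤ 0.01
is reported as significant, 0.01 < p ≤ 0.05 as a trend, larger p never as an
effect (a rule of thumb standing in for multiplicity correction when a
figure carries fewer than five comparisons — no correction is applied
automatically).  Subjects losing more than 75% of the trials of any
condition under either method are excluded (exactly 75% is retained), and no
significance is computed with fewer than 4 remaining subjects.

## Preprocessing operators

All operators are non-destructive and return new containers.

* **High-pass** — 4th-order Butterworth (per pass) or Hamming windowed-sinc
  FIR; two-pass forward–backward application by default, so the output is
  zero-phase and the cutoff is attenuated to half amplitude (−3 dB per
  pass).  The FIR length is `ceil(3.3·srate/tb)` rounded up to odd, with
  transition bandwidth `tb = max(cutoff, 1 Hz)` centred on the cutoff.
  Filtering is applied to continuous data, before epoching.
* **Notch** — band-stop with passband edges (48, 52) Hz by default;
  windowed-sinc FIR (2-Hz transitions) or Butterworth band-stop, both
  zero-phase.
* **Re-referencing** — `"average"`, `"median"`, an explicit channel list, or
  `"none"`; the reference is computed and subtracted per sample.
* **Baseline subtraction** — per channel and trial, the mean over a
  pre-stimulus interval is removed.
* **Line-noise channel detection** — Welch periodogram (1-s Hann segments,
  50% overlap), mean power within ±1 Hz of the mains frequency, log-scaled
  and robust-z-scored against the other channels (median / 1.4826·MAD);
  channels with z > 4 (default) are flagged.
* **Spherical-spline interpolation** — classic scalp-potential spline:
  order-4 Legendre weights, terms to degree 7, ridge regularisation 1e-5 on
  the good-channel kernel; detection and interpolation are meant to run on
  continuous data before epoching.
* **Peak-to-peak trial rejection** — default mode `"ptp"` drops trials where
  any channel's max − min exceeds the threshold (200 µV default); mode
  `"abs"` implements the ±threshold range convention.  The rejected fraction
  is returned for the subject-exclusion rule.

## Synthetic cohorts

The generator produces per-subject continuous recordings plus event tables
with the statistical structure the metric assumes of real data.  Defaults
(one number per knob, chosen once as a realistic mid-sized ERP study):

| component | default | rationale |
|---|---|---|
| channels / srate | 64 at 250 Hz | common high-density montage, the working rate of typical resampled datasets |
| trials per condition | 100 | between the small (≈90) and large (≈500) condition counts of typical datasets |
| background noise | 1/f, 10 µV RMS | canonical EEG spectrum and amplitude |
| drift | 20 µV RMS below 0.05 Hz | slow electrode/skin potentials comparable to or larger than the signal |
| line noise | 1 µV at 50 Hz, optional bad channels at 10× | visible but not dominant mains contamination |
| artifacts | 2/min, ±400 µV, 0.5 s Hann pulses | sparse blink/movement-scale transients |
| common ERP | 5 µV, both conditions | cancels in the contrast; keeps single trials realistic |
| effect | 5 µV Gaussian bump at 0.35 s, SD 50 ms | a strong condition contrast: most channels significant for a typical subject, matching the premise that a true effect is scalp-wide |
| topography | Gaussian random field, N(1, 0.5²), SE covariance length 1 on the unit sphere | a cheap stand-in for volume conduction — smooth, scalp-wide, non-uniform |
| between-subject amplitude SD | 1 µV | visible subject heterogeneity, as in real cohorts |
| trial jitter | ±20% uniform | trial-to-trial amplitude variability |
| ISI | uniform 1.8–2.2 s | go/no-go-style presentation; default epochs never overlap |

Electrode positions come from a deterministic Fibonacci spiral on the unit
sphere (no montage files).  Each channel's noise is normalised to exactly
the configured RMS.  Everything is reproducible from `(seed,
subject_index)`; per-subject ground truth (amplitude, topography, bad
channels) is recomputable without generating the data.

What the generator does **not** emulate: spatially correlated background
noise (channels are independent), realistic blink/EMG morphology, alpha
rhythms, non-stationarity beyond drift, or any forward head model.  Passing
tests therefore show that the statistics behave as designed under the
assumed additive model — not that any particular preprocessing choice is
optimal for real recordings.

### The power oracle

For clean configurations (no drift/artifacts), `expected_metric` predicts
the metric analytically.  Per channel, the effect size is the window-mean
effect amplitude divided by the SD of the window-mean noise; the expected
metric is the mean over channels of two-sided two-sample t power at that
effect size (noncentral-t, pooled df), with three refinements:

* the window-mean noise SD is derived exactly from the generator's spectral
  shaping (bin-wise 1/f weights × the squared Dirichlet kernel of the
  window average), optionally multiplied by the two-pass Butterworth
  high-pass power response when the analysis pipeline filters first;
* the ±20% trial jitter adds `m²·j²/3` to the effect-condition variance;
* the finite-pool inflation γ (above) rescales the critical value, so the
  oracle reproduces both the metric's power and its elevated null level.

The oracle is validated against an independent textbook power
implementation in the unbounded-pool limit and against simulation at the
study scale.

## Numerical choices

* Epoch windows are half-open in samples, onsets in seconds are rounded to
  the nearest sample, and time 0 is the event sample — event latencies that
  fall between samples cannot break the pipeline.
* The resampling engine turns each draw into a trial-count matrix and forms
  group moments by matrix multiplication, so one implementation serves the
  single-window metric and the 60-bin latency scan; repetitions are chunked
  to bound memory.  Results are bit-reproducible for a given seed.
* Bootstrap p-values are floored at `2/n_boot`; zero-variance differences
  report the floor (or 1 when the mean is also zero).
* Selected-window clipping at epoch edges warns rather than errors.

## Known limitations

* The metric's absolute value depends on trial counts through the
  resampling inflation; only like-for-like comparisons (same variant, same
  pools) are meaningful.
* The latency scan's bin means slightly favour effects whose width is
  comparable to the bin; very brief effects may straddle two bins.
* The percentile CI undercovers for small cohorts (a known property of the
  percentile bootstrap of a mean); the studentized p-value is calibrated
  down to small n, but the interval is reported in the plain percentile
  form and its nominal coverage is verified only at moderate cohort sizes.
* Channel-correlation-based bad-channel detection (as opposed to line-noise
  detection) is out of scope.
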