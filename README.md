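# erpsig

**A bootstrap-resampled data-quality metric for event-related EEG, with the
tooling to benchmark preprocessing pipelines against it.**

EEG preprocessing is full of defensible-sounding choices — high-pass cutoff,
referencing scheme, baseline interval, artifact thresholds — whose actual
effect on downstream statistics is rarely measured.  `erpsig` implements a
simple, label-free quality metric for two-condition ERP experiments: the
**percentage of significant channels**, i.e. the fraction of electrodes whose
window-averaged potential differs between conditions.  Because volume
conduction spreads any real cortical response across the whole scalp, a
cleaner recording should show the effect on more electrodes; a preprocessing
step is good exactly to the extent that it raises this percentage.

The package is aimed at EEG methodologists and pipeline authors.  It ships:

* the metric itself (`quality`): per-channel unpaired t-tests on window-mean
  potentials, averaged over 20 000 with-replacement resamples of 50 trials
  (or of all remaining trials), plus the 50-ms-step latency scan that selects
  the 100-ms window of maximum effect from the data;
* subject-paired bootstrap **method comparison** (`comparison`) with the
  field's exclusion and reporting rules;
* the minimal native **preprocessing operators** the metric is used to judge
  (`preprocessing`): zero-phase Butterworth / windowed-sinc high-pass, notch,
  average / median / channel re-referencing, baseline subtraction, line-noise
  channel detection, spherical-spline interpolation, peak-to-peak trial
  rejection;
* a **synthetic ERP cohort generator** (`synthetic`) with known ground truth
  and a closed-form noncentral-t power oracle, so every stage is testable
  without downloading data;
* lossless HDF5 containers + BIDS-style events TSV I/O (`data_model`) and an
  `erpsig` CLI.

## The statistic

For subject *s* with condition trial pools of sizes `T_a`, `T_b`, window
mean `x̄` over the selected 100-ms window:

```
for r = 1 .. 20 000:
    draw 50 trials with replacement from each condition
    per channel c:  t_c = (x̄_a − x̄_b) / s_pooled·√(1/50 + 1/50)
    P_r = 100 · #{c : p_c < 0.05} / C
metric_s = mean_r P_r
```

Methods are compared by bootstrapping the per-subject paired differences
(subjects as cases, 20 000 resamples): percentile 95% CI, studentized
bootstrap p-value, effects rounded to the nearest percent, p ≤ 0.01
significant, 0.01 < p ≤ 0.05 a trend.  Subjects losing > 75% of any
condition's trials to a rejection step are excluded; with < 4 subjects no
significance is computed.  See `docs/methods.md` for the full model,
including why the resampled metric's null level sits *above* the nominal α
for finite trial pools and how the oracle accounts for it.

## Worked example

Simulate one subject of a realistic cohort (1/f noise, drift, line noise,
artifacts, 5-µV effect at 0.35 s on a smooth random topography), high-pass
filter, epoch, and score:

```python
import erpsig as es

cfg = es.SyntheticConfig(n_subjects=2, n_channels=32, n_trials=100, seed=42)
rec, events = es.generate_subject(cfg, 0)
rec = es.highpass_filter(rec, es.FilterSpec(kind="butterworth", cutoff_hz=0.5))
a = es.extract_epochs(rec, events, "A", tmin=-0.3, tmax=0.7)
b = es.extract_epochs(rec, events, "B", tmin=-0.3, tmax=0.7)
res = es.SignificanceMetric(
    a, b, es.MetricConfig(window=(0.30, 0.40), n_boot=2000, seed=0)
).fit()
print(res.summary())
```

```
Resampled channel-significance metric
==========================================
subject            sub-000
mode               resample_50
channels           32
trials (a, b)      50, 50
window [s]         (0.3, 0.4)
alpha              0.05
resample size      50
repetitions        2000
significant [%]    80.92  (MC SE 0.099)
```

80.9% of this subject's channels show the condition difference — a clean,
strong-effect recording.  Comparing high-pass filtering against raw data on
a 6-subject cohort of the same design:

```python
cmp = es.paired_bootstrap_compare(hp_vals, raw_vals,
                                  es.ComparisonConfig(n_boot=20000, seed=1),
                                  name_a="hp0.5", name_b="raw")
print(cmp.summary())
```

```
Paired bootstrap comparison: hp0.5 - raw
================================================
subjects retained   6
mean difference     +51.72 percentage points
95% CI              (+42.81, +59.16)
p (bootstrap)       0.0161
label               trend
```

High-pass filtering raises the metric by ~52 percentage points on this
drifting cohort (labelled a trend rather than significant here only because
six subjects give the bootstrap little resolution below p = 0.01).

The same flows are available from the shell, deterministically for a fixed
seed:

```bash
erpsig --seed 7 --config sim.yaml simulate --out cohort/
erpsig --seed 3 metric --a a.h5 --b b.h5 --window 0.30 0.40 --out metric.json
erpsig --seed 1 scan --cohort manifest.tsv --out scan
erpsig compare --a-manifest a.tsv --b-manifest b.tsv --rejections rej.tsv
erpsig preprocess --in rec.h5 --out clean.h5 --steps hp:0.5,notch:48-52,linechan:4
```

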