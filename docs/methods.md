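# Methods

## Scientific setting

The package analyzes chronic dual-channel two-photon experiments in
mouse primary visual cortex: a red genetically encoded calcium
indicator (jRGECO1a-like) reports spiking activity of layer 2/3
neurons at ~10 Hz, while a green GFP reporter driven by an
immediate-early-gene (IEG) promoter — Arc, c-Fos, or EGR1 — reports
slow, activity-dependent gene expression sampled as snapshots on a
minutes (dark-adaptation protocol) or 12-hour (visuomotor-learning
protocol) grid.  The analyses quantify (i) how strongly and at what
time lag population activity predicts subsequent reporter expression,
(ii) how mean expression and expression *patterns* change across
learning conditions, and (iii) which functional cell types (visually
driven, motor-driven, mismatch, untuned) carry high expression of each
reporter.

Because the corresponding in vivo datasets are not redistributable,
every analysis is validated against a synthetic experiment generator
with complete ground truth.  The generator is first-class, tested code:
its parameters define the study conditions under which all
parameter-recovery results in the test suite hold.

## Analysis definitions

* **ΔF/F** — per neuron, `(F − median(F)) / median(F)` with the median
  taken per recording segment; an optional causal exponentially
  weighted smoothing filter (time constant 0.2 s, single parameter,
  toggleable) is applied afterwards.  Neurons with non-positive median
  raw fluorescence are excluded and logged.  Negative ΔF/F is kept.
* **Expression normalization** — per mouse, all ROI × timepoint
  measurements are shifted by their joint minimum and divided by the
  median of the shifted values, so the normalized matrix has minimum 0
  and median 1.  The map is idempotent and invariant to positive affine
  rescaling of the raw data.
* **Lagged population-vector correlation** — for each lag L on a
  uniform grid (default −2…+6 h in 15-min steps), every (activity
  timepoint, expression timepoint) pair whose time difference falls
  nearest to L contributes the Pearson correlation across neurons
  between the two population vectors; pair correlations are averaged
  per lag with equal weight (the simplest symmetric choice; recorded in
  output metadata).  Lags without pairs are reported missing, never
  zero.  Argmax ties break to the earliest lag.
* **Small-sample group comparison** — each group of per-mouse peak
  correlations is resampled with replacement 5 times (resampling unit =
  mouse, the unit the group sizes refer to; configurable), and a pooled
  two-sample t test is run on the pooled resampled values.  The
  resample draws and seed are logged in the result.
* **Condition-boundary change** — per mouse, mean of the first two
  sessions of the following condition minus mean of the last two
  sessions of the preceding condition; paired t test across mice.
* **Linear trend** — OLS of the per-mouse session means on time,
  treating each mouse-timepoint as an independent observation; R² and
  the overall-F p-value are reported, and the plotted line is the
  average of per-mouse first-degree fits.
* **Pattern similarity** — Spearman rank correlation across neurons
  between normalized expression vectors of every timepoint pair,
  averaged over mice (Kendall available behind a flag).  Because the
  statistic is rank-based it is invariant to any strictly monotone
  transform, so raw and normalized expression give identical matrices.
* **Event-triggered responses** — ΔF/F baseline-subtracted by the mean
  in −500…−100 ms before event onset, quantified as the mean over a
  1.5-s response window, averaged over events; events with truncated
  windows are dropped and logged.  Z-scores are computed over the
  pooled population of all neurons (pooled across sessions and mice of
  one reporter line, per condition).
* **High-IEG selection** — neurons ranked by mean normalized expression
  over the reference day (both sessions of the first day of condition
  3 by default; configurable); the top round-half-up(0.10 × N) are
  selected, ties broken toward the lower neuron id.  This reproduces
  the selected counts 197/1969 and 121/1213 exactly.

## Synthetic experiment generator

### Schedules

`dark_adapt_fig1`: 25 sessions spaced 15 min apart; the baseline
session is followed by a 15-min randomized grating block (8 directions
× 10 repetitions, 2 s standing + 3 s drifting each), then dark sessions
continue for 6 h.  The per-session activity recording duration is not
constrained by the protocol; the default is 120 s, a realistic snippet
given that expression imaging shares each 15-min slot.

`learning_fig2`: 12 sessions spaced 12 h apart, four per condition.
Condition 1 sessions are a single dark recording with expression
snapshots before and after; conditions 2 and 3 run
dark → closed-loop → open-loop → open-loop → dark → grating → dark
(seven recordings, default 480 s each).

### Behavior

Running is a two-state (rest/run) Markov chain with exponential dwell
times (defaults: mean bout 6 s, mean rest 8 s) and a first-order
speed filter toward a per-bout target (~15 cm/s); speed is exactly zero
at rest so onset detection has clean quiescent baselines.  Closed-loop
visual flow equals gain × running speed; 1-s flow halts (the mismatch
probe) are Poisson-proposed (default 0.05 Hz), accepted only while the
animal runs faster than 1 cm/s and at least 5 s after the previous
halt, because visuomotor mismatch is defined relative to ongoing
self-motion.  Open-loop segments replay the preceding closed-loop flow
sample-for-sample while running is generated afresh.

### Activity

Each neuron has a type (visual / motor / mismatch / untuned; default
fractions 0.30/0.30/0.15/0.25), lognormal tuning gains, a lognormal
baseline rate (mean 1.2 Hz), and a direction-tuned grating response
(von Mises concentration 1.5, standing gratings at 30 % of drifting).
The instantaneous rate is the rectified sum of baseline and tuned
drives, multiplied by a per-session excitability gain — a lognormal
AR(1) across sessions (σ = 1.3, ρ = 0.7, unit mean) that makes the
population activity pattern drift slowly over timepoints.  This slow
drift is the signal the coupling analysis recovers; its parameters were
calibrated (see below).  Spikes are an inhomogeneous Poisson process on
the 10-Hz grid; fluorescence is the spike train convolved with a
0.5-s single-exponential calcium kernel (ΔF/F ≈ 0.2 per spike) on a
baseline F0 ≈ 100, plus white noise at `snr_activity` (default 10).

### Gene induction

Raw expression of neuron *i* at snapshot time *t* is

    raw_i(t) = B_i + gain · d_i · Σ_s W(t, s) · g_cond(s) · u_i(s) + ε

where `u_i(s)` is the convex mixture `(1−w)·mean + w·max` of the
neuron's noise-free ΔF/F in session *s* (components standardized to a
common scale before mixing, so *w* is a variance-share weight;
default w = 0.5), `d_i` is a lognormal per-neuron drive with a
reporter-line bias (Arc-drive loads on visual tuning weights,
EGR1-drive on motor + mismatch weights, c-Fos is unbiased), and
`g_cond` is a per-condition drive gain (Arc 2.2× in condition 3,
EGR1 0.55×, c-Fos unchanged) that produces the learning-related
expression changes.  `B_i` is a lognormal baseline (sd 0.25) and ε is
white with SD = sd(coupled term)/`snr_ieg`.

The induction kernel is causal with an analytic peak: a gamma density
parameterized directly by its mode (`induction_delay_h`, default
3.5 h) and standard deviation (`induction_width_h`, default 0.5 h for
Arc and c-Fos, 1.5 h for EGR1 — which makes the EGR1 lag curve broad
and flat, as observed for that reporter), mixed with a 5 % exponential
reporter-persistence tail (time constant `ieg_decay_h` = 6 h) that
starts exactly at the mode, so both components peak at the configured
delay.

Animals live between recording sessions, so expression at a snapshot
reflects activity the microscope never saw.  The generator treats each
session's activity summary as the level of a piecewise-constant latent
activity process on blocks *centered* on the session times and
integrates the kernel analytically (via its CDF) over each block.
Centered blocks keep the recovered peak lag unbiased on the 15-min
grid; on the 12-h learning grid the same construction makes each
session's expression reflect predominantly that session's activity,
which is what makes same-session mean-vs-max comparisons meaningful.

### Calibration of the coupling defaults

The per-line defaults (`snr_ieg`, excitability σ and ρ, kernel width,
Arc line-selectivity) were calibrated once against a brute-force
simulation of the full pipeline so that default 4-mouse × 300-neuron
dark-adaptation cohorts recover mouse-averaged peak correlations of
≈ 0.39 (c-Fos), ≈ 0.26 (Arc) and ≈ 0.21 (EGR1), with the Arc/c-Fos
peak at the 3.5-h default delay.  The calibrated values are frozen in
`config.py` and are not tuned per run.

### Frame rendering

For imaging-module round-trip tests the generator paints traces
(red channel) and static expression (green channel) into
non-overlapping circular somata on a constant background with optional
white pixel noise; with zero noise, ROI extraction recovers the
injected values exactly.  Rendering uses one plane; the 4-plane piezo
scheme exists only as config metadata.

## What the generator does *not* emulate

No eye movements, neuropil contamination, motion artifacts or
registration errors; no orientation-tuning development or plasticity
mechanisms; the virtual-corridor geometry is reduced to a fixed
closed-loop gain; gene induction is a linear kernel on session-level
activity summaries, not a transcription model.  Passing recovery tests
therefore demonstrates that the *analysis chain* is correct and
well-calibrated under realistic noise, not that real cortical IEG
expression follows this generative law.

## Numerical choices and degenerate inputs

Pair-to-lag assignment uses the nearest grid lag within half a grid
step; argmax ties break to the earliest lag; constant population
vectors are dropped from pair averages; a constant expression matrix is
rejected by the normalization with a named error; zero-variance t tests
return flagged degenerate results (p = 1 for a zero difference);
rank-similarity rows for constant vectors are reported missing.  All
simulation outputs are bit-identical under a fixed seed and config, and
HDF5 files are written with timestamps disabled so identical runs are
byte-identical on disk.

## Problem sizes used in the test and acceptance runs

Parameter-recovery checks run on 4 mice × 300 neurons for the
dark-adaptation coupling analyses (20 seeded replicates), and on
reduced learning cohorts (2 mice × 120 neurons, 60-s segments, 2
grating repetitions) for the functional-enrichment orderings — sizes
chosen so the full validation suite runs on a laptop-class single CPU
while keeping every effect far above its sampling noise.  Null
calibrations use ≥ 2000 replicates per test.

## Known limitations

* The bootstrap+t group comparison inherits the small-sample quirks of
  a 5× bootstrap: its degrees of freedom refer to the pooled resampled
  values, and are reported explicitly rather than corrected.
* The mean/max mixture weight and the reporter-line drive biases are
  phenomenological devices that make the corresponding empirical
  contrasts reproducible by construction; they are not mechanistic
  claims.
* With 15-min sessions, same-session (lag-0) activity cannot influence
  same-session expression through the causal kernel, so
  dark-adaptation cohorts carry no lag-0 coupling by design.
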