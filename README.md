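# iegflow

Analysis pipeline for chronic two-photon experiments that image a red
calcium indicator together with a green immediate-early-gene (IEG)
reporter — Arc, c-Fos or EGR1 — in mouse visual cortex, plus a
ground-truth synthetic experiment generator used to validate every
stage by parameter recovery.

It is written for systems-neuroscience labs that record per-neuron
activity traces (~10 Hz ΔF/F) alongside reporter-expression snapshots
taken every 15 minutes (dark-adaptation protocol) or every 12 hours
across visuomotor learning (dark-reared mice passing through darkness →
first visual exposure → first normal visuomotor coupling), and want to
ask: *does activity predict later gene expression, with what lag and
strength; how do expression levels and patterns change with experience;
and which functional cell types express each gene most strongly?*

## Core quantities

* **ΔF/F**: `(F − median F) / median F` per neuron and segment, with an
  optional causal exponential smoothing filter.
* **Expression normalization** (per mouse, over all ROIs and
  timepoints jointly):

      ROInorm[i, tp] = (ROI[i, tp] − min) / (median − min)

  so the normalized matrix has minimum 0 and median 1.
* **Lagged population-vector correlation**: for lag L (positive =
  activity precedes expression), the Pearson correlation across neurons
  between the activity population vector at *t* and the expression
  population vector at *t + L*, averaged over all timepoint pairs at
  that lag and summarized by its peak lag and peak value per mouse.
* **Condition dynamics**: mean timecourses, condition-boundary changes
  (last two vs first two sessions), OLS linear trends with the
  overall-F test, and Spearman rank-order expression-pattern similarity
  matrices.
* **Functional characterization**: running-onset / grating-onset /
  visuomotor-mismatch event-triggered responses (baseline −500…−100 ms,
  response window 1.5 s) z-scored over the population, top-10 %
  high-expression neuron selection, and per-neuron running / visual-flow
  correlations during open-loop replay.

See `docs/methods.md` for the full model of the synthetic generator and
every numerical convention.

## Worked example

Simulate a default Arc dark-adaptation cohort (4 mice × 300 neurons,
25 timepoints at 15-min spacing) and recover the induction lag:

```python
import numpy as np
from iegflow import GeneratorConfig, cohort_correlation_curves, \
    mean_curve, peak_statistics
from iegflow.synthgen import simulate_cohort

cfg = GeneratorConfig.for_line("Arc")          # induction delay 3.5 h
mice = simulate_cohort(cfg, "dark_adapt_fig1", seed=1)
curves = cohort_correlation_curves(mice)       # one curve per mouse
stats = peak_statistics(curves)
mc = mean_curve(curves)
print("peak lag (mouse-averaged curve):",
      mc.lag_h[np.nanargmax(mc.r)], "h")
print("per-mouse peak r:", np.round(stats["peak_r"], 3))
print("mean peak r: %.3f +- %.3f" % (stats["peak_r_mean"],
                                     stats["peak_r_sem"]))
```

Output:

```
peak lag (mouse-averaged curve): 3.5 h
per-mouse peak r: [0.251 0.264 0.239 0.223]
mean peak r: 0.244 +- 0.009
```

The peak sits at the generator's 3.5-h induction delay, and the peak
correlation is in the weak-but-positive range characteristic of
mean-activity/expression coupling (the c-Fos preset couples more
strongly, ≈ 0.39; EGR1 more weakly, ≈ 0.21 with a broad flat lag
curve).

The same pipeline is available from the shell:

```bash
iegflow simulate --config run.yaml
iegflow extract  --config run.yaml
iegflow coupling --config run.yaml
iegflow dynamics --config run.yaml
iegflow responses --config run.yaml
iegflow report   --config run.yaml --plots
```

where `run.yaml` names the protocol (`fig1` / `fig2`), the generator
parameters, the seed and the output directory; every output embeds the
config hash and seed.

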