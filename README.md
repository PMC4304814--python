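# riderp

Conventional and latency-compensated (RIDE) analysis of event-related
potentials (ERPs), with a synthetic single-trial EEG generator and a
within-subjects statistics layer that make every stage testable without
access to raw recordings.

## The problem

An ERP is the average of EEG epochs time-locked to a stimulus.  When the
latency of a component (say the N400 or the P600) varies from trial to
trial, stimulus-locked averaging smears the component: a Gaussian bump of
width *w* under Gaussian latency jitter of SD *σ* keeps only

&nbsp;&nbsp;&nbsp;&nbsp;*w* / √(*w*² + *σ*²)

of its single-trial peak.  Cross-condition amplitude differences are
attenuated along with the components themselves, which can mask real
effects or blur their timing.

**Residue Iteration Decomposition (RIDE)** addresses this by splitting the
single trials into component clusters with distinct latency behaviour —
a stimulus-locked cluster **S**, an N400-range cluster **C1** (search
window 200–600 ms) and a P600-range cluster **C2** (400–800 ms).  Per-trial
C1/C2 latencies are initialized with Woody's adaptive template-matching
filter and then refined in alternation with the decomposition itself:

1. each cluster's waveform is the pointwise **median** over trials aligned
   to that cluster's latencies, after subtracting the current estimates of
   the other clusters (each shifted to its own trial latency), restricted
   to the cluster's search window;
2. each trial's C1/C2 latency is re-estimated by cross-correlating the
   residual (other clusters removed) with the cluster template.

After convergence the **reconstructed ERP** places every cluster at its
most probable (median) latency and sums them — an average with the
latency jitter compensated.

The package implements the emulated study design end to end: three
sentence conditions (congruent CON, semantic violation SEM, combined
semantic+syntactic violation SEM+SYN), a 38-channel 10–20 montage, epochs
of −200…1000 ms at 500 Hz, ±80 µV artifact screening, N400/P600 analysis
windows (300–500 ms; 570–810 ms conventional, 500–800 ms reconstructed),
and fully within-subjects ANOVAs (condition × electrode on the midline;
condition × region × hemisphere over six lateral ROIs) with
Greenhouse–Geisser correction, partial η², simple main effects and planned
pairwise comparisons.

## Worked example

```bash
python examples/smearing_and_recovery.py
```

simulates 200 trials of one Gaussian component (width 50 ms, single-trial
peak 5 µV, latency SD 50 ms, AR(1) noise) and prints:

```
analytic attenuation w/sqrt(w^2+s^2):   0.707
conventional average peak / true peak:  0.724
RIDE reconstruction peak / true peak:   0.997
estimated vs true single-trial latency r = 0.999
```

The conventional average loses ~30% of the peak, exactly as the
closed-form smearing factor predicts, while the reconstruction recovers
the single-trial amplitude and the per-trial latencies almost perfectly.
Other examples cover the generator (`simulate_dataset.py`), the ANOVA
layer (`rm_anova_demo.py`) and the full chain (`full_pipeline.py`); the
same chain is scriptable from a shell via the `riderp` CLI
(`simulate`, `preprocess`, `erp`, `ride`, `stats`, `run`).

```python
from riderp import SimConfig, simulate_trials, run_ride, average_evoked
epochs, truth = simulate_trials(SimConfig(seed=1, n_subjects=1))
result = run_ride(epochs[0].select_conditions("SEM"))
reconstructed = result.reconstructed        # Evoked: channels x time
latencies = result.clusters["C1"].latencies  # per-trial ms
```

## Layout

| Path | Contents |
| --- | --- |
| `src/riderp/core.py` | containers (Recording, EpochSet, Evoked, RoiLayout), filtering, re-referencing, epoching, baseline, artifact rejection |
| `src/riderp/io.py` | HDF5/TSV epoch containers, EDF adapter |
| `src/riderp/simulate.py` | synthetic single-trial generator with recorded ground truth |
| `src/riderp/erp.py` | averaging, grand averages, window means, topographies |
| `src/riderp/ride.py` | Woody latency estimation, RIDE decomposition, reconstruction |
| `src/riderp/stats.py` | rm-ANOVA + GG correction, effect sizes, pairwise, simple effects |
| `src/riderp/pipeline.py`, `cli.py` | end-to-end orchestration and the thin CLI |
| `docs/methods.md` | model, parameters, numerical choices, limitations |
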