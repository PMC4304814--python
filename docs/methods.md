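# Methods

## Data model and conventions

All epoched data live in an `EpochSet`: a `trials × channels × time`
tensor in microvolts with a millisecond time axis relative to stimulus
onset.  The time axis is uniform at 1000/fs ms; epochs are half-open on
the right at the sample level, so the default −200…1000 ms window at
500 Hz holds 600 samples at −200, −198, …, 998 ms.  Sample indices are
0-based internally; every reported latency is in ms.  The default montage
is a 38-site 10–20 layout with eight midline electrodes (FPz…Oz) and six
lateral ROIs of four electrodes each (anterior/central/posterior ×
left/right); the posterior ROIs use PO5/PO6, the parieto-occipital sites
the montage actually contains.  Idealized 2-D positions ship with the
layout for topography export and synthetic scalp weighting.

## Preprocessing

*Filtering.* The band-pass (default 0.02–30 Hz) applies the **two-pass
(squared) magnitude response of a 4th-order Butterworth design with zero
phase**, realized in the DCT domain (implicit even-symmetric extension).
A time-domain forward–backward IIR at a 0.02 Hz lower edge is
ill-conditioned — the poles sit within ~3×10⁻⁴ of the unit circle and the
edge-state transients (time constants near a minute) corrupt the passband
of finite records by 8–60% in direct measurements — whereas a real
multiplicative response is numerically exact, attenuates 100 Hz by
>40 dB, passes 10 Hz to within 0.1%, zeroes the DC bin exactly, and moves
a smooth bump's peak by 0 samples.  ERP latency comparisons require
exactly this phase neutrality.

*Re-referencing* subtracts the mean of the two mastoid channels from every
channel; the mastoid pair then averages to exactly zero.  *Baseline
correction* removes the per-trial, per-channel mean over [−200, 0) ms
(half-open, excluding the onset sample) and is idempotent.  *Artifact
rejection* removes a trial iff any scalp channel/sample exceeds ±80 µV
after re-referencing and baseline correction (the order is a package
choice); EOG channels are excluded from the screen, rejected trials are
dropped (never imputed) and per-condition counts are logged.  The
threshold is exclusive: a sample at exactly ±80 µV survives.

## Synthetic single-trial generator

Each trial is `Σ_c a_c(condition) · g_c(subject) · w_c(channel) ·
f_c(t − τ_c,trial) + noise`:

- `f_c` — unit bump (Gaussian, or half-cosine with compact support) of
  width *w* centred at *μ*;
- `τ` — per-trial latency from a truncated Gaussian (±3 SD, re-drawn on
  violation so components stay inside the epoch);
- `w_c` — per-channel gains from a Gaussian fall-off around a scalp
  position (centro-parietal for the late components, fronto-central for
  the early one);
- `g_c` — per-subject gain ~ N(1, 0.2), clipped at 0.3, shared across
  conditions within a component (realistic between-subject amplitude
  variability without condition confounds);
- noise — AR(1) with ρ = 0.95 scaled to a target SD (default 10 µV per
  channel), independently per channel and trial; white noise available.
  Autocorrelated noise was chosen because white noise is unrealistically
  favourable to latency estimation.

Default scenario (the emulated three-condition design): S at 170 ms,
width 45 ms, 4 µV in every condition, no jitter; C1 (N400-like, negative)
at 400 ms, width 60 ms, −5 µV in SEM and SEM+SYN, absent in CON, latency
SD 45 ms; C2 (P600-like, positive) at 650 ms, width 80 ms, 1/3/5 µV in
CON/SEM/SEM+SYN, latency SD 55 ms; 18 subjects × 40 trials/condition at
500 Hz.  The latency SDs are free parameters chosen mid-range of what is
plausible for late cognitive components (30–60 ms); nothing in the
emulated design pins them.  Every draw (latencies, amplitudes, gains,
contaminated trials) is recorded in a `GroundTruth` object, and a single
seeded generator drives the whole run, so identical configs are bitwise
reproducible.

What the generator does **not** emulate: volume-conducted (spatially
correlated) noise, eye blinks, alpha rhythms, component shape variability
across trials and subjects, and latency distributions other than the
truncated Gaussian.  Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not performance on
real recordings.

## RIDE

Clusters: S (stimulus-locked, latency fixed at 0), C1 with search window
[200, 600] ms and C2 with [400, 800] ms.  One latency per trial (the mean
of a configurable centro-parietal channel set, default Cz/CPz/Pz, drives
the estimation) is applied to all channels.  Shifts are integer-sample
(2 ms at 500 Hz), non-circular, with vacated samples zero-filled under a
50 ms cosine edge taper; cluster waveforms are restricted to their search
window with a 50 ms cosine roll-off.

*Initialization* — Woody's adaptive filter per cluster: template = trial
average within the window; per-trial latency = arg-max cross-correlation
within the admissible range (half the window width, so the implied
component position stays inside the window); template re-averaged at the
aligned latencies; repeat until the assignments stabilize.  Latencies are
median-centred.  Ties in the correlation break toward the smaller |lag|.

*Decomposition* — alternating scheme: per cluster, subtract the other
clusters (each shifted to its trial latencies), align the residual trials
to the cluster's latencies, estimate the waveform as the pointwise
**median** (robust to residual misalignment), apply the window mask.
Two numerical choices proved necessary:

1. **Zero-mean anchor.**  A constant inside a search window is invariant
   under shifting, so its split between S and a windowed cluster is not
   identified; the alternation then drifts instead of converging.
   Windowed clusters are anchored to zero mean over their window support
   (the constant share is carried by S; reconstructions are unchanged).
2. **Warm start.**  The inner loop resumes from the previous outer
   iteration's waveforms, so inner iterations accumulate across the run
   rather than restarting.

*Latency update* — cross-correlate the residual (other clusters removed)
with the cluster template inside the admissible range.  A trial keeps its
previous lag unless the best lag's correlation beats it by a 10% relative
margin (hysteresis): with noisy, weak components the arg-max otherwise
toggles between near-equivalent optima every iteration and the outer loop
cannot settle.

*Convergence* — the outer loop stops when the inner decomposition has met
its tolerance (relative waveform change < 10⁻³ against the norm of the
trial average) **and** the median absolute latency change is below one
sample; defaults cap at 10 outer × 12 inner iterations.  A cross-outer
waveform-stability criterion was deliberately not used: a cluster with no
true component (e.g. C1 in the congruent condition) realigns noise, and
its waveform never stabilizes to fine tolerance even though its latencies
do.  Runs that exhaust the caps return the best estimate flagged
`converged=False` with the residual-RMS trace retained; at realistic
noise (10 µV) this is the common, honest outcome, and the reconstruction
quality plateaus well before the caps.

*Reconstruction* — S + C1 + C2, each shifted to the median of its trial
latencies ("most probable latency"; the median is a package choice).
With zero jitter this equals the conventional average to numerical
precision.  RIDE runs separately per subject and per condition, as the
cross-condition comparisons require.

Known limitations: components separated only by overlapping windows and
different jitter are weakly identified for very smooth (low-frequency)
content — the shift-averaging operator has eigenvalues near 1 there, so a
broad residual can remain in S; sub-sample latency refinement is out of
scope; no response-locked cluster is provided (no responses occur at the
critical word in the emulated design).

## Conventional track and statistics

Window means are inclusive of the samples nearest to both millisecond
bounds (symmetric and reproducible; over the whole epoch the window mean
equals the time mean exactly).  Grand averages weight subjects equally by
default (`by_trials` optional).  Analysis windows: 300–500 ms in both
tracks; 570–810 ms conventional, 500–800 ms reconstructed.

The rm-ANOVA handles 1–3 crossed within factors on a balanced table (one
value per subject × cell; unbalanced input raises with the missing cells
listed).  Sums of squares follow the standard balanced partition (Möbius
inclusion–exclusion over marginal means); each effect is tested against
its own effect × subject interaction.  Greenhouse–Geisser ε is computed
per effect from the covariance of orthonormal-contrast scores
(ε = (Σλ)²/(q·Σλ²), clipped to [1/q, 1]) and the corrected p is reported
for every effect alongside the uncorrected one (no sphericity-test gate).
Effect size is partial η² = SS_eff/(SS_eff+SS_err).  Planned pairwise
comparisons are paired two-sided t-tests, uncorrected by default with
Holm optional; zero-variance difference pairs are flagged rather than
silently dropped.  Sums of squares below 10⁻¹² of the total SS are
treated as exact zeros (cancellation guard).  No between-subject factors
are supported (none occur in the design).

The Type-I calibration check runs at the statistics level — 18 subjects ×
3 conditions × 8 electrodes, null condition effect, condition-specific
error SDs (1.5/2.0/2.5 µV) to induce mild non-sphericity — because a
thousand full-chain replicates would add nothing about the test's
calibration while costing hours.

## Pipeline

`run_pipeline` chains simulate/load → preprocess → conventional averaging
→ RIDE → window amplitudes → ANOVAs/pairwise/simple effects → difference
topographies (SEM−CON, SEM+SYN−CON, SEM+SYN−SEM per window and track),
writing tidy CSVs, per-subject evokeds (HDF5), per-trial latencies, and a
manifest (config echo, hash, seed, versions, stage timings).  Identical
config + seed reproduces byte-identical CSVs.  A planned pairwise
comparison is also run on a pooled centro-parietal midline unit
(CPz/Pz/POz mean), where both late components project maximally.  Stage
failures abort with the stage name and move partial outputs under
`failed/`.

## Problem sizes in the shipped checks

The acceptance checks use the scenarios above at sizes chosen to be
statistically meaningful on a single CPU: 200 trials for the smearing /
completeness scenario (Monte-Carlo error on the peak ratio ≈ 0.01–0.02),
10 × 100 trials for latency recovery, 100 random designs for the ANOVA
oracle, 1000 replicates for Type-I calibration, and the full default
scenario (18 × 3 × 40 trials) for the end-to-end pattern.  The
decomposition-completeness scenario uses 0.25 µV noise: the conventional
average retains a σ/√n noise floor that no latency-locked model can
represent, so the achievable completeness error is bounded below by
roughly σ/(√n · RMS_signal) and the check is meaningful only when that
floor sits safely under the 2% criterion.
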