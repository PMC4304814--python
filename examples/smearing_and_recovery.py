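"""Latency jitter smears the average; RIDE reconstruction undoes it.

Simulates 200 trials of a single Gaussian component (width 50 ms, peak
5 uV) whose latency jitters with SD 50 ms, then compares the peak of the
conventional stimulus-locked average and of the RIDE reconstruction with
the analytic attenuation factor w / sqrt(w^2 + sigma^2).
"""
import numpy as np

from riderp import (
    ComponentSpec,
    SimConfig,
    average_evoked,
    default_layout,
    run_ride,
    simulate_trials,
    smearing_factor,
)

channels = ["Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]
comp = ComponentSpec(
    name="C1", mu=400.0, width=50.0, scalp_weights=np.ones(len(channels)),
    amplitude_by_condition={"SEM": 5.0}, latency_sd=50.0,
)
cfg = SimConfig(seed=11, n_subjects=1, trials_per_condition=200,
                conditions=("SEM",), components=[comp], noise_sd=0.25,
                channels=channels, subject_gain_sd=0.0)
epochs, truth = simulate_trials(cfg, default_layout())
es = epochs[0]

conv = average_evoked(es, "SEM")
result = run_ride(es)
cz = es.channel_index("Cz")

print(f"analytic attenuation w/sqrt(w^2+s^2):   {smearing_factor(50, 50):.3f}")
print(f"conventional average peak / true peak:  {conv.data[cz].max() / 5.0:.3f}")
print(f"RIDE reconstruction peak / true peak:   {result.reconstructed.data[cz].max() / 5.0:.3f}")
r = np.corrcoef(result.clusters["C1"].latencies,
                truth.latencies["C1"][0] - np.median(truth.latencies["C1"][0]))[0, 1]
print(f"estimated vs true single-trial latency r = {r:.3f}")
# the conventional peak lands near the analytic 0.707 attenuation, while
# the reconstruction recovers ~the full single-trial amplitude because the
# trials are re-aligned before averaging.
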