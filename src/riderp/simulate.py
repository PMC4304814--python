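"""Synthetic single-trial EEG with known component structure.

Each simulated trial is a sum of scalp-weighted component bumps plus
broadband noise:

    x_i(ch, t) = sum_c  a_c(condition_i) * g_s(subject) * w_c(ch)
                        * f_c(t - tau_{c,i})  +  noise(ch, t)

where ``f_c`` is a unit-amplitude bump (Gaussian or half-cosine) of width
``w`` centred at ``mu``, ``tau_{c,i}`` is a per-trial latency drawn from a
truncated Gaussian (SD ``latency_sd``, +/- 3 SD), ``w_c`` are per-channel
gains in [-1, 1], and the noise is AR(1) (default rho = 0.95, scaled to a
target SD) or white.  Every random draw is recorded in a
:class:`GroundTruth` so that recovery can be tested against it.

The default scenario emulates the three-condition sentence-violation
design: a stimulus-locked early cluster (S), an N400-like negative bump
(C1) around 400 ms that is equal in SEM and SEM+SYN and absent in CON, and
a P600-like positive bump (C2) around 650 ms ordered SEM+SYN > SEM > CON,
both with centro-parietal topographies and trial-to-trial latency jitter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .core import CONDITIONS, EpochSet, ParameterError, RoiLayout, default_layout

__all__ = [
    "ComponentSpec",
    "SimConfig",
    "GroundTruth",
    "component_waveform",
    "simulate_trials",
    "smearing_factor",
    "gaussian_scalp_weights",
    "default_components",
    "default_config",
    "simulate_null_amplitudes",
]


def smearing_factor(w: float, sigma: float) -> float:
    """Expected peak attenuation of a Gaussian bump under Gaussian jitter.

    Averaging trials whose Gaussian bump of width ``w`` (ms) is jittered
    with SD ``sigma`` (ms) convolves the bump with the latency density,
    widening it to ``sqrt(w**2 + sigma**2)`` and scaling its peak by

        w / sqrt(w**2 + sigma**2).
    """
    if w <= 0:
        raise ParameterError("bump width must be positive")
    if sigma < 0:
        raise ParameterError("jitter SD must be non-negative")
    return w / math.sqrt(w * w + sigma * sigma)


def gaussian_scalp_weights(
    layout: RoiLayout, channels: list[str], center: tuple[float, float], spread: float = 0.7
) -> np.ndarray:
    """Per-channel gains from a Gaussian fall-off around a scalp position."""
    pos = layout.positions
    out = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch in pos:
            d2 = (pos[ch][0] - center[0]) ** 2 + (pos[ch][1] - center[1]) ** 2
            out[i] = math.exp(-d2 / (2 * spread * spread))
    return out


@dataclass
class ComponentSpec:
    """One simulated component cluster.

    ``amplitude_by_condition`` is in microvolts (sign carries polarity);
    ``latency_sd`` and ``latency_shift_by_condition`` are in ms.  S-type
    (stimulus-locked) components have ``latency_sd = 0``.
    """

    name: str
    mu: float
    width: float
    scalp_weights: np.ndarray
    amplitude_by_condition: dict[str, float]
    shape: str = "gaussian"
    latency_sd: float = 0.0
    latency_shift_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError("component width must be positive")
        if self.latency_sd < 0:
            raise ParameterError("latency_sd must be non-negative")
        self.scalp_weights = np.asarray(self.scalp_weights, dtype=float)

    def bump(self, times: np.ndarray, shift_ms: float = 0.0) -> np.ndarray:
        """Unit-amplitude time course, peak at ``mu + shift_ms``."""
        t = times - self.mu - shift_ms
        if self.shape == "gaussian":
            return np.exp(-0.5 * (t / self.width) ** 2)
        if self.shape == "halfcosine":
            out = np.zeros_like(t)
            sel = np.abs(t) <= self.width
            out[sel] = 0.5 * (1 + np.cos(np.pi * t[sel] / self.width))
            return out
        raise ParameterError(f"unknown shape family {self.shape!r}")


def component_waveform(
    spec: ComponentSpec, times: np.ndarray, amplitude: float = 1.0
) -> np.ndarray:
    """Deterministic channel x time matrix for one component.

    Peak value at ``t = mu`` equals ``amplitude * scalp_weight`` per channel;
    for the Gaussian family the waveform is below 1% of peak beyond
    ``mu +/- 4 width``.
    """
    times = np.asarray(times, dtype=float)
    if not (times[0] <= spec.mu <= times[-1]):
        raise ParameterError(f"component centre {spec.mu} ms outside epoch")
    return amplitude * np.outer(spec.scalp_weights, spec.bump(times))


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults mirror the emulated design)."""

    seed: int
    n_subjects: int = 18
    trials_per_condition: int = 40
    fs: float = 500.0
    window: tuple[float, float] = (-200.0, 1000.0)
    conditions: tuple[str, ...] = CONDITIONS
    components: list[ComponentSpec] | None = None
    noise_sd: float = 10.0
    noise_model: str = "ar1"
    ar_coef: float = 0.95
    subject_gain_sd: float = 0.2
    channels: list[str] | None = None
    include_mastoids: bool = False
    n_contaminated: int = 0
    contamination_uv: float = 120.0

    def resolve(self, layout: RoiLayout | None = None):
        layout = layout or default_layout()
        channels = list(self.channels) if self.channels else list(layout.channels)
        if self.include_mastoids:
            channels = channels + [m for m in layout.mastoids if m not in channels]
        comps = self.components
        if comps is None:
            comps = default_components(layout, channels)
        return layout, channels, comps


@dataclass
class GroundTruth:
    """Everything that was drawn while generating a dataset."""

    latencies: dict[str, np.ndarray]  # component -> (n_subjects, n_trials) ms
    amplitudes: dict[str, np.ndarray]  # component -> (n_subjects, n_trials) uV
    subject_gains: dict[str, np.ndarray]  # component -> (n_subjects,)
    waveforms: dict[str, np.ndarray]  # component -> channel x time, unit amplitude
    conditions: np.ndarray  # (n_subjects, n_trials) labels
    contaminated: list[tuple[int, int]]  # (subject_index, trial_index)
    seed: int


def default_components(layout: RoiLayout, channels: list[str]) -> list[ComponentSpec]:
    """S / C1 / C2 specification of the default scenario.

    S: early exogenous fronto-central bump, stimulus-locked, condition-blind.
    C1: N400-like negativity at 400 ms, equal in SEM and SEM+SYN, absent in
    CON, latency SD 45 ms.  C2: P600-like centro-parietal positivity at
    650 ms ordered SEM+SYN > SEM > CON, latency SD 55 ms.  Amplitudes are
    single-trial peaks in microvolts at the topography maximum.
    """
    cp = gaussian_scalp_weights(layout, channels, center=(0.0, -0.55), spread=0.75)
    fc = gaussian_scalp_weights(layout, channels, center=(0.0, 0.25), spread=0.75)
    return [
        ComponentSpec(
            name="S", mu=170.0, width=45.0, scalp_weights=fc,
            amplitude_by_condition={c: 4.0 for c in CONDITIONS},
        ),
        ComponentSpec(
            name="C1", mu=400.0, width=60.0, scalp_weights=cp,
            amplitude_by_condition={"CON": 0.0, "SEM": -5.0, "SEM+SYN": -5.0},
            latency_sd=45.0,
        ),
        ComponentSpec(
            name="C2", mu=650.0, width=80.0, scalp_weights=cp,
            amplitude_by_condition={"CON": 1.0, "SEM": 3.0, "SEM+SYN": 5.0},
            latency_sd=55.0,
        ),
    ]


def default_config(seed: int, **overrides) -> SimConfig:
    """Default-scenario :class:`SimConfig` with keyword overrides."""
    return replace(SimConfig(seed=seed), **overrides)


def _truncated_normal(rng, sd: float, size: int, bound_sd: float = 3.0) -> np.ndarray:
    """Gaussian draws re-drawn until within +/- bound_sd * sd (keeps bumps in-epoch)."""
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > bound_sd * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > bound_sd * sd
    return out


def _noise(rng, shape, sd, model, rho):
    if sd == 0:
        return np.zeros(shape)
    if model == "white":
        return rng.normal(0.0, sd, shape)
    if model == "ar1":
        e = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), shape)
        x0 = rng.normal(0.0, sd, shape[:-1])
        zi = (rho * x0)[..., None]
        out, _ = _signal.lfilter([1.0], [1.0, -rho], e, axis=-1, zi=zi)
        return out
    raise ParameterError(f"unknown noise model {model!r}")


def simulate_trials(
    cfg: SimConfig, layout: RoiLayout | None = None
) -> tuple[list[EpochSet], GroundTruth]:
    """Generate one :class:`EpochSet` per subject plus the ground truth.

    A single seeded generator drives every draw, so identical configs give
    bitwise-identical output.  Condition order is randomized per subject.
    Optionally ``n_contaminated`` trials per subject receive a planted
    artifact spike (``contamination_uv``) for rejection tests.
    """
    layout, channels, comps = cfg.resolve(layout)
    fs, (w0, w1) = cfg.fs, cfg.window
    times = np.arange(int(round(w0 * fs / 1000.0)), int(round(w1 * fs / 1000.0))) * (
        1000.0 / fs
    )
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.trials_per_condition * len(cfg.conditions)

    truth = GroundTruth(
        latencies={c.name: np.zeros((cfg.n_subjects, n_trials)) for c in comps},
        amplitudes={c.name: np.zeros((cfg.n_subjects, n_trials)) for c in comps},
        subject_gains={
            c.name: np.clip(rng.normal(1.0, cfg.subject_gain_sd, cfg.n_subjects), 0.3, None)
            for c in comps
        },
        waveforms={c.name: component_waveform(c, times) for c in comps},
        conditions=np.empty((cfg.n_subjects, n_trials), dtype=object),
        contaminated=[],
        seed=cfg.seed,
    )

    epochsets = []
    for s in range(cfg.n_subjects):
        conds = np.repeat(cfg.conditions, cfg.trials_per_condition)
        rng.shuffle(conds)
        truth.conditions[s] = conds
        data = _noise(rng, (n_trials, len(channels), len(times)), cfg.noise_sd,
                      cfg.noise_model, cfg.ar_coef)
        for comp in comps:
            lat = _truncated_normal(rng, comp.latency_sd, n_trials)
            shift = np.array(
                [comp.latency_shift_by_condition.get(str(c), 0.0) for c in conds]
            )
            amp = np.array(
                [comp.amplitude_by_condition.get(str(c), 0.0) for c in conds]
            ) * truth.subject_gains[comp.name][s]
            truth.latencies[comp.name][s] = lat + shift
            truth.amplitudes[comp.name][s] = amp
            # analytic evaluation at the shifted centre: continuous latencies
            bumps = np.stack([comp.bump(times, lv) for lv in lat + shift])
            data += amp[:, None, None] * comp.scalp_weights[None, :, None] * bumps[:, None, :]
        if cfg.n_contaminated:
            picks = rng.choice(n_trials, size=cfg.n_contaminated, replace=False)
            for tr in picks:
                ch = int(rng.integers(len(channels)))
                t0 = int(rng.integers(len(times) - 10))
                data[tr, ch, t0 : t0 + 10] += cfg.contamination_uv
                truth.contaminated.append((s, int(tr)))
        epochsets.append(
            EpochSet(
                data=data,
                times=times,
                conditions=conds.astype(object),
                subject_id=f"S{s + 1:02d}",
                montage=channels,
            )
        )
    return epochsets, truth


def simulate_null_amplitudes(
    rng: np.random.Generator,
    n_subjects: int = 18,
    n_conditions: int = 3,
    n_units: int = 8,
) -> np.ndarray:
    """Null window-amplitude tensor (subject x condition x unit), no condition effect.

    Subject intercepts and a fixed unit (electrode) profile plus noise whose
    SD differs by condition level (1.5/2.0/2.5 uV cycled) — a mildly
    non-spherical null for testing Type-I control of the corrected ANOVA.
    """
    subj = rng.normal(0.0, 2.0, (n_subjects, 1, 1))
    unit = rng.normal(0.0, 1.0, (1, 1, n_units))
    sds = np.array([1.5 + (i % 3) * 0.5 for i in range(n_conditions)])
    noise = rng.normal(0.0, 1.0, (n_subjects, n_conditions, n_units)) * sds[None, :, None]
    return subj + unit + noise
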