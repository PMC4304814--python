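"""Residue Iteration Decomposition (RIDE) of single-trial ERPs.

RIDE separates epoched single trials into component clusters with distinct
trial-to-trial latency behaviour: a stimulus-locked cluster **S**, and two
latency-variable clusters **C1** (N400 complex, search window 200-600 ms)
and **C2** (P600 complex, search window 400-800 ms).  Per-trial latencies
of C1 and C2 are first estimated with Woody's adaptive template-matching
filter, then the decomposition and the latency estimates are refined in
alternation:

1. *Decomposition* — each cluster's waveform is the pointwise **median**
   over trials aligned to that cluster's latencies, after subtracting the
   current estimates of the other clusters (each shifted to its own
   per-trial latency); the waveform is restricted to the cluster's search
   window with a cosine roll-off.
2. *Latency update* — each trial's C1/C2 latency is re-estimated by
   cross-correlating the residual (other clusters removed) with the
   cluster template inside the admissible shift range.

Iteration stops when the median latency change drops below one sample and
the waveforms stabilize.  The latency-compensated ("reconstructed") ERP is
the sum of the cluster waveforms, each placed at the most probable (median)
single-trial latency — undoing the amplitude smearing that latency jitter
inflicts on the conventional average.

All shifts are integer-sample (2 ms at 500 Hz); shifted-out samples are
dropped and vacated samples are zero-filled under a cosine edge taper.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .core import EpochSet, Evoked, ParameterError

__all__ = [
    "RideConfig",
    "ComponentCluster",
    "RideResult",
    "shift_waveform",
    "woody_latency",
    "decompose_components",
    "update_latencies",
    "run_ride",
    "run_ride_by_condition",
    "reconstruct_erp",
]

_TINY = 1e-12


@dataclass
class RideConfig:
    """Tunable parameters of the decomposition.

    Search windows are in ms post-stimulus; ``latency_channels`` drive the
    latency estimation (their mean is the matching signal); ``taper_ms`` is
    the cosine roll-off width at window and shift edges.  ``pre_smooth_hz``
    optionally low-passes the matching signal (estimation only; the
    decomposition always sees the unsmoothed data).
    """

    c1_window: tuple[float, float] = (200.0, 600.0)
    c2_window: tuple[float, float] = (400.0, 800.0)
    s_window: tuple[float, float] | None = None  # None = whole epoch
    latency_channels: tuple[str, ...] = ("Cz", "CPz", "Pz")
    max_outer: int = 10
    max_inner: int = 12
    tol: float = 1e-3
    taper_ms: float = 50.0
    woody_max_iter: int = 25
    pre_smooth_hz: float | None = None
    #: relative correlation margin a new lag must win by before a trial's
    #: latency moves; suppresses noise-driven toggling between near-ties
    lag_hysteresis: float = 0.1

    def windows(self) -> dict[str, tuple[float, float] | None]:
        return {"S": self.s_window, "C1": self.c1_window, "C2": self.c2_window}

    def __post_init__(self):
        if self.tol <= 0:
            raise ParameterError("tolerance must be positive")


@dataclass
class ComponentCluster:
    """One converged cluster: waveform in its aligned frame + trial latencies."""

    name: str
    waveform: np.ndarray  # channel x time, uV
    latencies: np.ndarray  # per-trial ms (S: all zero), median-centred
    window: tuple[float, float] | None


@dataclass
class RideResult:
    clusters: dict[str, ComponentCluster]
    reconstructed: Evoked
    n_iterations: int
    converged: bool
    residual_rms: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shifting primitives


def _cos_ramp(n: int) -> np.ndarray:
    # half-cosine 0 -> 1 over n samples
    return 0.5 * (1 - np.cos(np.pi * (np.arange(n) + 1) / (n + 1)))


def _shift_samples(arr: np.ndarray, d: int, taper: int) -> np.ndarray:
    """Shift along the last axis by ``d`` samples; zero-fill with edge taper."""
    out = np.zeros_like(arr)
    n = arr.shape[-1]
    if d == 0:
        return arr.copy()
    if abs(d) >= n:
        return out
    if d > 0:
        out[..., d:] = arr[..., : n - d]
        k = min(taper, n - d)
        if k:
            out[..., d : d + k] *= _cos_ramp(k)
    else:
        out[..., : n + d] = arr[..., -d:]
        k = min(taper, n + d)
        if k:
            out[..., n + d - k : n + d] *= _cos_ramp(k)[::-1]
    return out


def shift_waveform(
    w: np.ndarray, delta_ms: float, fs: float, taper_ms: float = 50.0
) -> np.ndarray:
    """Shift a channel x time waveform by ``delta_ms`` (positive = later).

    Non-circular: samples shifted past the epoch edge are dropped and the
    vacated samples are zero-filled under a cosine taper of ``taper_ms``.
    """
    if not np.isfinite(delta_ms):
        raise ParameterError("shift must be finite")
    d = int(round(delta_ms * fs / 1000.0))
    return _shift_samples(np.asarray(w, dtype=float), d, int(round(taper_ms * fs / 1000.0)))


def _stack_shifted(w: np.ndarray, d_samples: np.ndarray, taper: int) -> np.ndarray:
    """(n_trials, ...) stack of one waveform shifted to each trial's latency."""
    out = np.empty((len(d_samples),) + w.shape, dtype=w.dtype)
    for d in np.unique(d_samples):
        out[d_samples == d] = _shift_samples(w, int(d), taper)
    return out


def _shift_trials(X: np.ndarray, d_samples: np.ndarray, taper: int) -> np.ndarray:
    """Shift each trial of (n_trials, n_ch, n_t) by its own lag."""
    out = np.empty_like(X)
    for d in np.unique(d_samples):
        sel = d_samples == d
        out[sel] = _shift_samples(X[sel], int(d), taper)
    return out


# ---------------------------------------------------------------------------
# latency estimation


def _window_indices(times: np.ndarray, window) -> tuple[int, int]:
    i0 = int(np.argmin(np.abs(times - window[0])))
    i1 = int(np.argmin(np.abs(times - window[1])))
    if i1 <= i0:
        raise ParameterError(f"window {window} is empty")
    return i0, i1


def _window_mask(times: np.ndarray, window, taper_ms: float) -> np.ndarray:
    """1 inside the window, cosine roll-off of ``taper_ms`` outside, 0 beyond."""
    if window is None:
        return np.ones_like(times)
    mask = np.zeros_like(times)
    w0, w1 = window
    mask[(times >= w0) & (times <= w1)] = 1.0
    if taper_ms > 0:
        lo = (times >= w0 - taper_ms) & (times < w0)
        hi = (times > w1) & (times <= w1 + taper_ms)
        mask[lo] = 0.5 * (1 + np.cos(np.pi * (w0 - times[lo]) / taper_ms))
        mask[hi] = 0.5 * (1 + np.cos(np.pi * (times[hi] - w1) / taper_ms))
    return mask


def _latency_signal(x: EpochSet, channels, pre_smooth_hz=None) -> np.ndarray:
    idx = [x.channel_index(c) for c in channels]
    sig = x.data[:, idx, :].mean(axis=1)
    if pre_smooth_hz:
        sos = _sig.butter(4, pre_smooth_hz, btype="lowpass", fs=x.fs, output="sos")
        sig = _sig.sosfiltfilt(sos, sig, axis=-1, padlen=min(27, sig.shape[-1] - 1))
    return sig


def _best_lag(
    sig_tr: np.ndarray,
    template: np.ndarray,
    i0: int,
    max_lag: int,
    prev_lag: int | None = None,
    hysteresis: float = 0.0,
) -> int:
    """Arg-max cross-correlation lag; ties broken toward the smaller |lag|.

    With ``prev_lag``/``hysteresis`` the previous lag is kept unless the
    best lag's score exceeds the previous lag's score by ``hysteresis``
    times the best score magnitude (stabilizes noise-dominated trials).
    """
    scores = np.correlate(sig_tr, template, mode="valid")  # index p = template start
    lags = np.arange(len(scores)) - i0
    ok = np.abs(lags) <= max_lag
    lags, scores = lags[ok], scores[ok]
    order = np.lexsort((np.abs(lags), -scores))
    best = order[0]
    if prev_lag is not None and hysteresis > 0:
        prev_idx = np.flatnonzero(lags == prev_lag)
        if prev_idx.size:
            margin = hysteresis * abs(float(scores[best]))
            if float(scores[best]) - float(scores[prev_idx[0]]) <= margin:
                return int(prev_lag)
    return int(lags[best])


def _median_centre(d: np.ndarray, max_lag: int) -> np.ndarray:
    d = d - int(round(float(np.median(d))))
    return np.clip(d, -max_lag, max_lag)


def woody_latency(
    x: EpochSet,
    window: tuple[float, float],
    latency_channels=("Cz", "CPz", "Pz"),
    max_iter: int = 25,
    pre_smooth_hz: float | None = None,
) -> np.ndarray:
    """Per-trial component latency by Woody's adaptive filter (ms).

    The template starts as the trial average over ``latency_channels``
    restricted to ``window``; each trial's latency is the arg-max of the
    cross-correlation between template and trial within the admissible
    shift range (half the window width); the template is then re-averaged
    at the aligned latencies and the procedure repeats until the latency
    assignments stabilize.  Returned latencies are median-centred.
    """
    if x.n_trials < 2:
        raise ParameterError("Woody latency estimation needs at least 2 trials")
    sig = _latency_signal(x, latency_channels, pre_smooth_hz)
    i0, i1 = _window_indices(x.times, window)
    L = i1 - i0 + 1
    max_lag = L // 2
    n_t = sig.shape[-1]
    flat = sig.std(axis=-1) == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} flat trial(s): latency set to 0")
    d = np.zeros(x.n_trials, dtype=int)
    template = sig[:, i0 : i1 + 1].mean(axis=0)
    for _ in range(max_iter):
        d_new = np.array(
            [
                0 if flat[i] else _best_lag(sig[i], template, i0, max_lag)
                for i in range(x.n_trials)
            ]
        )
        # keep the template span inside the epoch when re-averaging
        d_new = np.clip(d_new, -i0, n_t - 1 - i1)
        if np.array_equal(d_new, d):
            break
        d = d_new
        template = np.stack(
            [sig[i, i0 + d[i] : i1 + 1 + d[i]] for i in range(x.n_trials)]
        ).mean(axis=0)
    d = _median_centre(d, max_lag)
    return d * 1000.0 / x.fs


# ---------------------------------------------------------------------------
# decomposition


def _lat_samples(lat_ms: np.ndarray, fs: float) -> np.ndarray:
    return np.round(np.asarray(lat_ms) * fs / 1000.0).astype(int)


def decompose_components(
    x: EpochSet,
    latencies: dict[str, np.ndarray],
    cfg: RideConfig,
    init: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], bool]:
    """Estimate S/C1/C2 waveforms given per-trial latency sets.

    Iterative subtraction scheme: for each cluster in turn, all trials are
    aligned to that cluster's latencies after removing the current
    estimates of the other clusters (each shifted to its own trial
    latency); the cluster waveform is the pointwise median across the
    aligned trials, restricted to its search window with a cosine
    roll-off.  Latency-variable (windowed) clusters are anchored to zero
    mean over their window support: a constant inside the window is
    invariant under shifting, so without the anchor the split of that
    constant between S and C1/C2 is unidentified and the alternation
    drifts.  The loop repeats until the largest waveform change, relative
    to the norm of the trial average, falls below ``cfg.tol``.  ``init``
    warm-starts the waveforms (used by the outer loop).  Returns the
    waveforms and a convergence flag.
    """
    names = [n for n in ("S", "C1", "C2") if n in latencies]
    fs, times = x.fs, x.times
    taper = int(round(cfg.taper_ms * fs / 1000.0))
    d = {n: _lat_samples(latencies[n], fs) for n in names}
    masks = {n: _window_mask(times, cfg.windows().get(n), cfg.taper_ms) for n in names}
    support = {n: masks[n] > 0.999 for n in names}
    # median is only needed where the mask is nonzero (contiguous span)
    spans = {}
    for n in names:
        nz = np.flatnonzero(masks[n] > 0)
        spans[n] = slice(int(nz[0]), int(nz[-1]) + 1)
    X = x.data.astype(np.float32)  # decomposition workspace
    if init is not None:
        waves = {n: init[n].astype(np.float32) for n in names}
    else:
        waves = {n: np.zeros((x.n_channels, len(times)), dtype=np.float32) for n in names}
    scale = float(np.linalg.norm(X.mean(axis=0))) + _TINY
    converged = False
    # maintain the summed per-trial model incrementally: each cluster's
    # residual is then data - model + its own shifted contribution
    shifted = {n: _stack_shifted(waves[n], d[n], taper) for n in names}
    model = np.sum(list(shifted.values()), axis=0)
    for _ in range(cfg.max_inner):
        max_change = 0.0
        for name in names:
            R = X - model
            R += shifted[name]
            aligned = _shift_trials(R, -d[name], taper)
            sl = spans[name]
            w_new = np.zeros_like(waves[name])
            w_new[:, sl] = np.median(aligned[:, :, sl], axis=0)
            if cfg.windows().get(name) is not None:
                w_new[:, sl] -= w_new[:, support[name]].mean(axis=1, keepdims=True)
            w_new *= masks[name].astype(np.float32)
            max_change = max(max_change, float(np.linalg.norm(w_new - waves[name])) / scale)
            waves[name] = w_new
            new_shifted = _stack_shifted(w_new, d[name], taper)
            model += new_shifted - shifted[name]
            shifted[name] = new_shifted
        if max_change < cfg.tol:
            converged = True
            break
    return {n: waves[n].astype(float) for n in names}, converged


def update_latencies(
    x: EpochSet,
    clusters: dict[str, np.ndarray],
    latencies: dict[str, np.ndarray],
    target: str,
    cfg: RideConfig,
) -> np.ndarray:
    """Re-estimate per-trial latencies of ``target`` (C1 or C2), in ms.

    Per trial the other clusters (shifted to their current latencies) are
    subtracted, the residual is averaged over the latency channel set, and
    cross-correlated with the target template inside the admissible window;
    the arg-max lag wins, ties toward the smaller |lag|.  The result is
    median-centred.  An all-zero template leaves latencies unchanged.
    """
    if target not in ("C1", "C2"):
        raise ParameterError("latency update targets C1 or C2 only")
    fs, times = x.fs, x.times
    window = cfg.windows()[target]
    i0, i1 = _window_indices(times, window)
    max_lag = (i1 - i0 + 1) // 2
    template = clusters[target][
        [x.channel_index(c) for c in cfg.latency_channels], i0 : i1 + 1
    ].mean(axis=0)
    if np.linalg.norm(template) < _TINY:
        warnings.warn(f"{target} template is all-zero; latencies unchanged")
        return np.asarray(latencies[target], dtype=float)
    taper = int(round(cfg.taper_ms * fs / 1000.0))
    others = [n for n in clusters if n != target]
    R = x.data.copy()
    for other in others:
        R -= _stack_shifted(clusters[other], _lat_samples(latencies[other], fs), taper)
    idx = [x.channel_index(c) for c in cfg.latency_channels]
    sig = R[:, idx, :].mean(axis=1)
    if cfg.pre_smooth_hz:
        sos = _sig.butter(4, cfg.pre_smooth_hz, btype="lowpass", fs=fs, output="sos")
        sig = _sig.sosfiltfilt(sos, sig, axis=-1, padlen=min(27, sig.shape[-1] - 1))
    prev = _lat_samples(latencies[target], fs)
    d = np.array(
        [
            _best_lag(sig[i], template, i0, max_lag, int(prev[i]), cfg.lag_hysteresis)
            for i in range(x.n_trials)
        ]
    )
    d = _median_centre(d, max_lag)
    return d * 1000.0 / fs


def run_ride(x: EpochSet, cfg: RideConfig | None = None) -> RideResult:
    """Full RIDE on one epoch set (one subject, one condition).

    Woody initialization of C1/C2 latencies, then alternation of
    :func:`decompose_components` and :func:`update_latencies` until the
    median absolute latency change is below one sample and the waveforms
    are stable (or ``max_outer`` is reached, in which case the best
    estimate is returned flagged as not converged).
    """
    cfg = cfg or RideConfig()
    if x.n_trials < 10:
        warnings.warn(f"RIDE on {x.n_trials} trials; >= 10 recommended")
    fs = x.fs
    taper = int(round(cfg.taper_ms * fs / 1000.0))
    lats = {
        "S": np.zeros(x.n_trials),
        "C1": woody_latency(x, cfg.c1_window, cfg.latency_channels,
                            cfg.woody_max_iter, cfg.pre_smooth_hz),
        "C2": woody_latency(x, cfg.c2_window, cfg.latency_channels,
                            cfg.woody_max_iter, cfg.pre_smooth_hz),
    }
    sample_ms = 1000.0 / fs
    prev_waves = None
    waves = None
    converged = False
    residual_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, cfg.max_outer + 1):
        waves, inner_converged = decompose_components(x, lats, cfg, init=prev_waves)
        new_lats = dict(lats)
        med_change = 0.0
        for target in ("C1", "C2"):
            new_lats[target] = update_latencies(x, waves, lats, target, cfg)
            med_change = max(
                med_change, float(np.median(np.abs(new_lats[target] - lats[target])))
            )
        resid = x.data.copy()
        for n in waves:
            resid -= _stack_shifted(waves[n], _lat_samples(new_lats[n], fs), taper)
        residual_trace.append(float(np.sqrt(np.mean(resid**2))))
        lats = new_lats
        # converged once the decomposition has settled (inner tolerance) and
        # the typical trial latency no longer moves by a full sample; a
        # waveform-stability criterion across outer iterations is not used
        # because clusters without a true component never satisfy one (their
        # noise-fit alignment keeps flipping between equivalent optima).
        if inner_converged and med_change < sample_ms:
            converged = True
            break
        prev_waves = waves
    clusters = {
        name: ComponentCluster(
            name=name,
            waveform=waves[name],
            latencies=np.asarray(lats[name], dtype=float),
            window=cfg.windows().get(name),
        )
        for name in waves
    }
    result = RideResult(
        clusters=clusters,
        reconstructed=None,  # filled below
        n_iterations=n_iter,
        converged=converged,
        residual_rms=residual_trace,
    )
    result.reconstructed = reconstruct_erp(result, x, cfg)
    return result


def reconstruct_erp(r: RideResult, x: EpochSet, cfg: RideConfig | None = None) -> Evoked:
    """Latency-compensated ERP: each cluster at its most probable latency.

    The most probable latency is the median of the cluster's single-trial
    latencies (zero after median-centring), so the reconstruction is the
    sum of the cluster waveforms each shifted to its median latency.
    """
    cfg = cfg or RideConfig()
    fs = x.fs
    data = np.zeros((x.n_channels, len(x.times)))
    for name, cl in r.clusters.items():
        med = float(np.median(cl.latencies))
        data += shift_waveform(cl.waveform, med, fs, cfg.taper_ms)
    conds = np.unique(x.conditions.astype(str))
    return Evoked(
        data=data,
        times=x.times,
        condition=conds[0] if len(conds) == 1 else "all",
        n_trials=x.n_trials,
        montage=list(x.montage),
    )


def run_ride_by_condition(
    x: EpochSet, cfg: RideConfig | None = None
) -> dict[str, RideResult]:
    """Run RIDE separately per condition (the cross-condition comparison basis)."""
    out = {}
    for cond in np.unique(x.conditions.astype(str)):
        out[str(cond)] = run_ride(x.select_conditions(str(cond)), cfg)
    return out
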