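"""Core data containers and preprocessing for epoched multi-channel EEG.

The common currency of the package is the :class:`EpochSet`: a
``trials x channels x time`` tensor of amplitudes in microvolts with a
millisecond time axis relative to stimulus onset and one condition label
per trial.  Continuous data live in a :class:`Recording` and are cut into
epochs with :func:`epoch_and_baseline`.

Preprocessing follows standard ERP practice: zero-phase band-pass
filtering, re-referencing to the average of the two mastoids, baseline
correction over the pre-stimulus interval, and rejection of trials whose
amplitude exceeds a fixed threshold on any scalp channel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import signal

logger = logging.getLogger(__name__)

#: Condition labels of the sentence-violation design: congruent control,
#: semantic violation, and combined semantic + syntactic violation.
CONDITIONS = ("CON", "SEM", "SEM+SYN")


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class FormatError(ValueError):
    """A file does not match the documented layout."""


class ParameterError(ValueError):
    """A parameter is outside its admissible range."""


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from the montage."""


class EmptyResultError(RuntimeError):
    """An operation removed every trial, leaving nothing to average."""


def _is_eog(label: str) -> bool:
    return label.upper().startswith(("EOG", "VEOG", "HEOG"))


# ---------------------------------------------------------------------------
# containers


@dataclass
class Recording:
    """Continuous multi-channel recording with stimulus events.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-20 channel names, unique.
    events : list of (int, str)
        ``(sample_index, condition)`` pairs marking stimulus onsets.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValidationError("channel_labels length must match samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel_labels must be unique")
        n = self.samples.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValidationError(f"event sample index {idx} outside record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class EpochSet:
    """Single-trial EEG tensor with channel labels and condition labels.

    ``data`` is ``(n_trials, n_channels, n_times)`` in microvolts; ``times``
    is in milliseconds relative to stimulus onset with a uniform step of
    ``1000 / fs``.
    """

    data: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    subject_id: str = "S00"
    montage: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValidationError("data must be 3-D (trials x channels x time)")
        if self.times.shape != (self.data.shape[2],):
            raise ValidationError("times length must match data time axis")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValidationError("times must be strictly increasing and uniform")
        if self.conditions.shape != (self.data.shape[0],):
            raise ValidationError(
                f"conditions length {self.conditions.shape} does not match "
                f"trial count {self.data.shape[0]}"
            )
        if self.montage and len(self.montage) != self.data.shape[1]:
            raise ValidationError("montage length must match channel axis")

    # -- convenience -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def fs(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.montage.index(label)
        except ValueError:
            raise ChannelNotFoundError(label) from None

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def select_conditions(self, labels) -> "EpochSet":
        labels = [labels] if isinstance(labels, str) else list(labels)
        keep = np.isin(self.conditions.astype(str), labels)
        return replace(self, data=self.data[keep], conditions=self.conditions[keep])

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            conditions=self.conditions.copy(),
            montage=list(self.montage),
        )


@dataclass
class Evoked:
    """Per-condition channel x time average (conventional or reconstructed)."""

    data: np.ndarray
    times: np.ndarray
    condition: str
    n_trials: int
    montage: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("Evoked data must be 2-D (channels x time)")
        if self.times.shape != (self.data.shape[1],):
            raise ValidationError("times length must match data")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")

    def channel_index(self, label: str) -> int:
        try:
            return self.montage.index(label)
        except ValueError:
            raise ChannelNotFoundError(label) from None

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times - t_ms)))


@dataclass
class RoiLayout:
    """Scalp layout: midline electrodes, lateral ROIs, mastoid pair, positions.

    The six lateral ROIs (anterior/central/posterior x left/right) hold four
    electrodes each and are pairwise disjoint; ``regions`` groups them by
    anterior-posterior band for the three-factor ANOVA design.
    """

    channels: list[str]
    midline: list[str]
    rois: dict[str, list[str]]
    mastoids: tuple[str, str]
    regions: dict[str, list[str]] = field(default_factory=dict)
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self):
        seen: set[str] = set()
        for roi, members in self.rois.items():
            for ch in members:
                if ch in seen:
                    raise ValidationError(f"ROIs are not disjoint: {ch}")
                if ch not in self.channels:
                    raise ValidationError(f"ROI {roi} member {ch} not in montage")
                seen.add(ch)
        for ch in self.midline:
            if ch not in self.channels:
                raise ValidationError(f"midline electrode {ch} not in montage")

    def roi_hemisphere(self, roi: str) -> str:
        return "left" if roi.startswith("left") else "right"

    def roi_region(self, roi: str) -> str:
        for region, members in self.regions.items():
            if roi in members:
                return region
        raise KeyError(roi)


def default_layout() -> RoiLayout:
    """The shipped 38-site 10-20 layout (8 midline sites, six lateral ROIs)."""
    with resources.files("riderp.data").joinpath("montage_38.yaml").open() as fh:
        return load_layout(fh)


def load_layout(source) -> RoiLayout:
    """Load a :class:`RoiLayout` from a YAML file path or open stream."""
    if hasattr(source, "read"):
        spec = yaml.safe_load(source)
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    return RoiLayout(
        channels=list(spec["channels"]),
        midline=list(spec["midline"]),
        rois={k: list(v) for k, v in spec["rois"].items()},
        mastoids=tuple(spec.get("mastoids", ())),
        regions={k: list(v) for k, v in spec.get("regions", {}).items()},
        positions={k: tuple(v) for k, v in spec.get("positions", {}).items()},
        name=spec.get("name", "custom"),
    )


# ---------------------------------------------------------------------------
# preprocessing


def _bandpass_sos(low: float, high: float, fs: float):
    if not 0 <= low < high:
        raise ParameterError("need 0 <= low < high")
    if high >= fs / 2:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {fs / 2} Hz")
    if low == 0:
        return signal.butter(4, high, btype="lowpass", fs=fs, output="sos")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _apply_zero_phase(data: np.ndarray, sos, fs: float) -> np.ndarray:
    """Apply the squared Butterworth magnitude response with zero phase.

    Response-equivalent to forward-backward IIR filtering, but realized in
    the DCT domain (implicit even-symmetric extension, so no endpoint
    discontinuity): the time-domain realization of a 0.02 Hz high-pass is
    numerically ill-conditioned (poles within ~3e-4 of the unit circle,
    edge-transient time constants near a minute) and corrupts the passband
    on finite records.  A real multiplicative response is exactly
    phase-neutral, and the DC bin gain of the band-pass is exactly 0.
    """
    from scipy.fft import dct, idct

    n = data.shape[-1]
    freqs = np.arange(n) * fs / (2.0 * n)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2  # forward + backward pass
    coef = dct(data, type=2, axis=-1, norm="ortho") * gain
    return idct(coef, type=2, axis=-1, norm="ortho")


def bandpass_filter(x, low: float = 0.02, high: float = 30.0):
    """Zero-phase 4th-order Butterworth band-pass, applied per channel.

    The two-pass (squared) magnitude response of the Butterworth design is
    applied with zero phase, so component peak latencies are preserved.
    Accepts a :class:`Recording` or an :class:`EpochSet` (filtered per
    trial) and returns the same type.
    """
    if isinstance(x, Recording):
        fs = x.fs
    elif isinstance(x, EpochSet):
        fs = x.fs
    else:
        raise TypeError("expected Recording or EpochSet")
    sos = _bandpass_sos(low, high, fs)
    if isinstance(x, Recording):
        # channel loop keeps memory bounded on long continuous recordings
        filtered = np.stack([_apply_zero_phase(ch, sos, fs) for ch in x.samples])
        return replace(x, samples=filtered)
    return replace(x, data=_apply_zero_phase(x.data, sos, fs))


def rereference(x: EpochSet, mastoids: tuple[str, str] | None = None) -> EpochSet:
    """Re-reference to the average of the two mastoid channels.

    Subtracts the mean of the two mastoid channels from every channel at
    every time point, after which the mastoid pair averages to exactly zero.
    """
    if mastoids is None:
        mastoids = ("M1", "M2")
    i1, i2 = (x.channel_index(m) for m in mastoids)
    ref = 0.5 * (x.data[:, i1, :] + x.data[:, i2, :])
    return replace(x, data=x.data - ref[:, None, :])


def baseline_correct(x: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline interval.

    The baseline window is half-open, ``[start, stop)`` in ms, so the
    default (-200, 0) excludes the stimulus-onset sample.  Idempotent.
    """
    sel = (x.times >= baseline[0]) & (x.times < baseline[1])
    if not sel.any():
        raise ParameterError(f"baseline window {baseline} contains no samples")
    mean = x.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(x, data=x.data - mean)


def epoch_and_baseline(
    r: Recording,
    window: tuple[float, float] = (-200.0, 1000.0),
    baseline: tuple[float, float] | None = (-200.0, 0.0),
    subject_id: str = "S00",
) -> EpochSet:
    """Cut stimulus-locked epochs from a continuous recording.

    The epoch window is half-open on the right at the sample level: a
    (-200, 1000) ms window at 500 Hz yields 600 samples at -200, -198, ...,
    998 ms.  Events too close to the record edge for the full window are
    skipped with a log message.  Baseline correction (mean of the baseline
    interval removed per trial and channel) is applied unless ``baseline``
    is None.
    """
    fs = r.fs
    i_pre = int(round(window[0] * fs / 1000.0))
    i_post = int(round(window[1] * fs / 1000.0))
    if i_post <= i_pre:
        raise ParameterError("empty epoch window")
    n_t = r.samples.shape[1]
    times = (np.arange(i_pre, i_post) * 1000.0 / fs).astype(float)
    epochs, labels, skipped = [], [], 0
    for onset, cond in r.events:
        lo, hi = onset + i_pre, onset + i_post
        if lo < 0 or hi > n_t:
            skipped += 1
            logger.warning("event at sample %d too close to record edge; skipped", onset)
            continue
        epochs.append(r.samples[:, lo:hi])
        labels.append(cond)
    if skipped:
        logger.info("skipped %d/%d events at record edges", skipped, len(r.events))
    if not epochs:
        raise EmptyResultError("no event leaves room for the full epoch window")
    es = EpochSet(
        data=np.stack(epochs),
        times=times,
        conditions=np.array(labels, dtype=object),
        subject_id=subject_id,
        montage=list(r.channel_labels),
    )
    es.n_skipped = skipped
    if baseline is not None:
        es = baseline_correct(es, baseline)
        es.n_skipped = skipped
    return es


def reject_artifacts(
    x: EpochSet,
    threshold: float = 80.0,
    exclude_channels: list[str] | None = None,
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose amplitude exceeds ``threshold`` microvolts.

    A trial is rejected iff any scalp channel/sample has ``|amplitude| >
    threshold``.  EOG channels (and any in ``exclude_channels``) are not
    screened.  Returns the surviving trials and a boolean mask over the
    original trials, True where rejected.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    excluded = set(exclude_channels or [])
    scalp = [
        i
        for i, lb in enumerate(x.montage or [f"ch{i}" for i in range(x.n_channels)])
        if lb not in excluded and not _is_eog(lb)
    ]
    rejected = np.abs(x.data[:, scalp, :]).max(axis=(1, 2)) > threshold
    if rejected.all():
        raise EmptyResultError("artifact rejection removed every trial")
    kept = replace(x, data=x.data[~rejected], conditions=x.conditions[~rejected])
    if rejected.any():
        per_cond = {
            c: int(np.sum(rejected & (x.conditions.astype(str) == c)))
            for c in np.unique(x.conditions.astype(str))
        }
        logger.info("rejected %d trials (by condition: %s)", rejected.sum(), per_cond)
    return kept, rejected
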