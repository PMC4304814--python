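"""Conventional stimulus-locked ERP analysis.

Averaging across trials, grand averages across subjects, mean-amplitude
extraction over analysis windows (per electrode or per ROI), and
per-channel difference topographies.  Default analysis windows follow the
two-window convention of the sentence-violation design: 300-500 ms for the
N400 range and 570-810 ms for the P600 range (500-800 ms on the
latency-compensated track).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EmptyResultError, EpochSet, Evoked, ParameterError, RoiLayout

__all__ = [
    "N400_WINDOW",
    "P600_WINDOW_CONVENTIONAL",
    "P600_WINDOW_RECONSTRUCTED",
    "WindowAmplitude",
    "average_evoked",
    "grand_average",
    "window_mean",
    "difference_topography",
    "long_table",
]

N400_WINDOW = (300.0, 500.0)
P600_WINDOW_CONVENTIONAL = (570.0, 810.0)
P600_WINDOW_RECONSTRUCTED = (500.0, 800.0)


@dataclass
class WindowAmplitude:
    subject_id: str
    condition: str
    unit: str  # electrode label or ROI name
    window: tuple[float, float]
    mean_amplitude: float


def average_evoked(x: EpochSet, condition: str) -> Evoked:
    """Pointwise mean across the trials of one condition."""
    sel = x.conditions.astype(str) == condition
    if not sel.any():
        raise EmptyResultError(f"no trials with condition {condition!r}")
    return Evoked(
        data=x.data[sel].mean(axis=0),
        times=x.times,
        condition=condition,
        n_trials=int(sel.sum()),
        montage=list(x.montage),
    )


def grand_average(evokeds: list[Evoked], weighting: str = "equal_subject") -> Evoked:
    """Average evokeds across subjects (equal weight, or weighted by trials)."""
    if not evokeds:
        raise EmptyResultError("no evokeds to average")
    ref = evokeds[0]
    for e in evokeds[1:]:
        if e.data.shape != ref.data.shape or not np.array_equal(e.times, ref.times):
            raise ParameterError("evokeds have mismatching channel/time axes")
    stack = np.stack([e.data for e in evokeds])
    n = np.array([e.n_trials for e in evokeds], dtype=float)
    if weighting == "equal_subject":
        data = stack.mean(axis=0)
    elif weighting == "by_trials":
        data = (stack * n[:, None, None]).sum(axis=0) / n.sum()
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    return Evoked(
        data=data,
        times=ref.times,
        condition=ref.condition,
        n_trials=int(n.sum()),
        montage=list(ref.montage),
    )


def _window_slice(times: np.ndarray, window) -> slice:
    # inclusive of the samples nearest to both millisecond bounds
    i0 = int(np.argmin(np.abs(times - window[0])))
    i1 = int(np.argmin(np.abs(times - window[1])))
    if i1 < i0:
        raise ParameterError(f"window {window} is empty after discretization")
    return slice(i0, i1 + 1)


def window_mean(
    e: Evoked,
    window: tuple[float, float],
    units,
    layout: RoiLayout | None = None,
    subject_id: str | None = None,
) -> list[WindowAmplitude]:
    """Mean amplitude over an analysis window, per electrode or ROI.

    Time samples at both window boundaries are included (nearest sample to
    each ms bound).  ``units`` is a list of electrode labels and/or ROI
    names; a ROI is resolved through ``layout`` and averaged over time
    first, then over its member electrodes.
    """
    sl = _window_slice(e.times, window)
    out = []
    for unit in units:
        if layout is not None and unit in layout.rois:
            chans = [e.channel_index(ch) for ch in layout.rois[unit]]
        else:
            chans = [e.channel_index(unit)]
        val = float(e.data[chans, sl].mean())
        out.append(
            WindowAmplitude(
                subject_id=subject_id or "",
                condition=e.condition,
                unit=unit,
                window=(float(window[0]), float(window[1])),
                mean_amplitude=val,
            )
        )
    return out


def difference_topography(
    a: Evoked, b: Evoked, window: tuple[float, float]
) -> pd.Series:
    """Per-channel window mean of (a - b); index = channel label."""
    if a.data.shape != b.data.shape or not np.array_equal(a.times, b.times):
        raise ParameterError("evokeds have mismatching channel/time axes")
    sl = _window_slice(a.times, window)
    vals = (a.data[:, sl] - b.data[:, sl]).mean(axis=1)
    labels = a.montage or [f"ch{i}" for i in range(a.data.shape[0])]
    return pd.Series(vals, index=labels, name=f"{a.condition}-{b.condition}")


def long_table(
    evokeds_by_subject: dict[str, dict[str, Evoked]],
    window: tuple[float, float],
    units,
    layout: RoiLayout | None = None,
) -> pd.DataFrame:
    """Tidy table of window amplitudes: subject, condition, unit, amplitude.

    ``evokeds_by_subject`` maps subject id -> condition -> Evoked.  When the
    units are lateral ROIs and a layout is given, ``region`` and
    ``hemisphere`` columns are added for the three-factor ANOVA design.
    """
    rows = []
    for sid, by_cond in evokeds_by_subject.items():
        for cond, ev in by_cond.items():
            for wa in window_mean(ev, window, units, layout, subject_id=sid):
                rows.append(
                    dict(
                        subject=sid,
                        condition=cond,
                        unit=wa.unit,
                        window_start=wa.window[0],
                        window_end=wa.window[1],
                        amplitude=wa.mean_amplitude,
                    )
                )
    df = pd.DataFrame(rows)
    if layout is not None and not df.empty and df["unit"].isin(layout.rois).all():
        df["region"] = [layout.roi_region(u) for u in df["unit"]]
        df["hemisphere"] = [layout.roi_hemisphere(u) for u in df["unit"]]
    return df
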