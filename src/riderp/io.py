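"""Reading and writing epoched EEG.

Two native epoch containers are supported:

* **HDF5** — datasets ``data`` (trial x channel x time, float32, microvolts),
  ``times`` (ms) and ``conditions`` (strings); file attributes ``fs``,
  ``subject_id`` and ``montage``.
* **TSV** — one row per trial-channel; columns ``trial``, ``channel``,
  ``condition`` followed by one column per time point named ``t<ms>``.
  ``# subject_id: ...`` may appear as a leading comment line.

Continuous EDF recordings are adapted through :mod:`mne` together with a
separate events table (TSV with columns ``sample_index``, ``condition``)
and are cut into epochs on load.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    EpochSet,
    FormatError,
    Recording,
    ValidationError,
    epoch_and_baseline,
)

__all__ = ["read_epochs", "write_epochs", "read_edf_recording"]


def _check_conditions(conds, allowed):
    if allowed is None:
        return
    unknown = sorted(set(map(str, conds)) - set(allowed))
    if unknown:
        raise ValidationError(f"unknown condition label(s): {unknown}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {
        ".h5": "hdf5", ".hdf5": "hdf5", ".hdf": "hdf5",
        ".tsv": "tsv", ".txt": "tsv",
        ".edf": "edf",
    }.get(suffix, "hdf5")


def write_epochs(x: EpochSet, path, format: str | None = None) -> Path:
    """Write an :class:`EpochSet` to HDF5 or TSV (inferred from the suffix)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=x.data.astype(np.float32))
            f.create_dataset("times", data=x.times)
            f.create_dataset(
                "conditions", data=np.array([str(c) for c in x.conditions], dtype="S")
            )
            f.attrs["fs"] = x.fs
            f.attrs["subject_id"] = x.subject_id
            f.attrs["montage"] = [str(c) for c in x.montage]
    elif fmt == "tsv":
        cols = [f"t{t:g}" for t in x.times]
        rows = []
        for tr in range(x.n_trials):
            for ch in range(x.n_channels):
                rows.append(
                    [tr, x.montage[ch] if x.montage else f"ch{ch}", str(x.conditions[tr])]
                    + list(x.data[tr, ch])
                )
        df = pd.DataFrame(rows, columns=["trial", "channel", "condition"] + cols)
        with open(path, "w") as fh:
            fh.write(f"# subject_id: {x.subject_id}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise FormatError(f"cannot write format {fmt!r}")
    return path


def _read_hdf5(path: Path, conditions_allowed) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "conditions"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        data = np.asarray(f["data"], dtype=float)
        times = np.asarray(f["times"], dtype=float)
        conds = [c.decode() if isinstance(c, bytes) else str(c) for c in f["conditions"][()]]
        if data.ndim != 3:
            raise FormatError(f"{path}: 'data' must be 3-D, got shape {data.shape}")
        if len(conds) != data.shape[0]:
            raise ValidationError(
                f"{path}: 'conditions' has {len(conds)} entries for "
                f"{data.shape[0]} trials"
            )
        _check_conditions(conds, conditions_allowed)
        return EpochSet(
            data=data,
            times=times,
            conditions=np.array(conds, dtype=object),
            subject_id=str(f.attrs.get("subject_id", "S00")),
            montage=[
                m.decode() if isinstance(m, bytes) else str(m)
                for m in f.attrs.get("montage", [])
            ],
        )


def _read_tsv(path: Path, conditions_allowed) -> EpochSet:
    subject_id = "S00"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "subject_id:" in line:
                subject_id = line.split("subject_id:", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    for col in ("trial", "channel", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    tcols = [c for c in df.columns if c.startswith("t") and c not in ("trial",)]
    tcols = [c for c in tcols if c[1:].lstrip("-").replace(".", "").isdigit()]
    if not tcols:
        raise FormatError(f"{path}: no time columns (expected names like 't-200')")
    times = np.array([float(c[1:]) for c in tcols])
    trials = sorted(df["trial"].unique())
    channels = list(df[df["trial"] == trials[0]]["channel"])
    data = np.empty((len(trials), len(channels), len(tcols)))
    conds = []
    for ti, tr in enumerate(trials):
        sub = df[df["trial"] == tr].set_index("channel")
        if list(sub.index) != channels:
            raise FormatError(f"{path}: trial {tr} channel set differs from trial 0")
        data[ti] = sub[tcols].to_numpy()
        conds.append(str(sub["condition"].iloc[0]))
    _check_conditions(conds, conditions_allowed)
    return EpochSet(
        data=data,
        times=times,
        conditions=np.array(conds, dtype=object),
        subject_id=subject_id,
        montage=channels,
    )


def read_edf_recording(path, events_path) -> Recording:
    """Read a continuous EDF file plus an events TSV into a :class:`Recording`.

    The events file needs columns ``sample_index`` and ``condition``.
    Amplitudes are converted from volts (mne's internal unit) to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    ev = pd.read_csv(events_path, sep="\t")
    for col in ("sample_index", "condition"):
        if col not in ev.columns:
            raise FormatError(f"{events_path}: missing column {col!r}")
    events = [(int(r.sample_index), str(r.condition)) for r in ev.itertuples()]
    return Recording(
        samples=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def read_epochs(
    path,
    format: str | None = None,
    events_path=None,
    window: tuple[float, float] = (-200.0, 1000.0),
    baseline: tuple[float, float] | None = (-200.0, 0.0),
    conditions_allowed: tuple[str, ...] | None = CONDITIONS,
) -> EpochSet:
    """Load an :class:`EpochSet` from HDF5, TSV, or (continuous) EDF.

    EDF input additionally requires ``events_path`` and cuts epochs with
    ``window``/``baseline``.  Condition labels are validated against
    ``conditions_allowed`` (pass None to accept any label).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _read_hdf5(path, conditions_allowed)
    if fmt == "tsv":
        return _read_tsv(path, conditions_allowed)
    if fmt == "edf":
        if events_path is None:
            raise FormatError("EDF input requires an events table (events_path=...)")
        rec = read_edf_recording(path, events_path)
        _check_conditions([c for _, c in rec.events], conditions_allowed)
        return epoch_and_baseline(rec, window=window, baseline=baseline,
                                  subject_id=path.stem)
    raise FormatError(f"unknown format {fmt!r}")
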