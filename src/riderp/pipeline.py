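"""End-to-end orchestration: simulate (or load) -> preprocess -> conventional
ERP -> RIDE -> window amplitudes -> statistics -> report tables.

Every run is driven by a :class:`PipelineConfig` (YAML-serializable) and a
single seed; identical config + seed reproduces byte-identical CSV output.
The two analysis tracks share the early window (300-500 ms); the late
window is 570-810 ms on the conventional track and 500-800 ms on the
latency-compensated (reconstructed) track.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    EpochSet,
    RoiLayout,
    baseline_correct,
    bandpass_filter,
    default_layout,
    reject_artifacts,
    rereference,
)
from .erp import (
    N400_WINDOW,
    P600_WINDOW_CONVENTIONAL,
    P600_WINDOW_RECONSTRUCTED,
    average_evoked,
    difference_topography,
    grand_average,
    long_table,
)
from .io import read_epochs
from .ride import RideConfig, run_ride_by_condition
from .simulate import SimConfig, simulate_trials
from .stats import planned_pairwise, rm_anova, simple_effects

logger = logging.getLogger(__name__)

#: midline electrodes pooled into the centro-parietal unit used for the
#: planned condition comparisons
CP_POOL = ("CPz", "Pz", "POz")


def _jsonable(obj):
    """Recursively convert config contents to JSON-serializable types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "pipeline_out"
    source: str = "simulate"  # or "files"
    input_files: list[str] = field(default_factory=list)
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    filter_data: bool = False  # synthetic data is already band-limited
    filter_band: tuple[float, float] = (0.02, 30.0)
    artifact_threshold: float = 80.0
    baseline: tuple[float, float] = (-200.0, 0.0)
    ride: dict = field(default_factory=dict)  # RideConfig overrides
    tracks: tuple[str, ...] = ("conventional", "reconstructed")
    windows: dict = field(
        default_factory=lambda: {
            "conventional": {"early": N400_WINDOW, "late": P600_WINDOW_CONVENTIONAL},
            "reconstructed": {"early": N400_WINDOW, "late": P600_WINDOW_RECONSTRUCTED},
        }
    )
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw and raw.get("source", "simulate") == "simulate":
            raise ValueError("a seed is required when simulating")
        return cls(**raw)

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


@dataclass
class PipelineResult:
    out_dir: Path
    evokeds: dict  # track -> subject -> condition -> Evoked
    tables: dict  # (track, window, design) -> long DataFrame
    anovas: dict  # (track, window, design) -> ANOVA DataFrame
    pairwise: dict  # (track, window) -> DataFrame
    simple: dict  # (track, window) -> roi -> DataFrame
    topographies: dict  # (track, window) -> DataFrame channel x contrast
    manifest: dict


# ---------------------------------------------------------------------------
# stages


def load_or_simulate(cfg: PipelineConfig, layout: RoiLayout) -> list[EpochSet]:
    if cfg.source == "simulate":
        sim = SimConfig(seed=cfg.seed, **cfg.sim)
        epochs, _ = simulate_trials(sim, layout)
        return epochs
    if cfg.source == "files":
        if not cfg.input_files:
            raise ValueError("source='files' but no input_files configured")
        return [read_epochs(p) for p in cfg.input_files]
    raise ValueError(f"unknown source {cfg.source!r}")


def preprocess(cfg: PipelineConfig, epochs: list[EpochSet]) -> list[EpochSet]:
    """Filter (optional), re-reference (if mastoids present), baseline, reject."""
    out = []
    for es in epochs:
        if cfg.filter_data:
            es = bandpass_filter(es, *cfg.filter_band)
        if all(m in es.montage for m in ("M1", "M2")):
            es = rereference(es, ("M1", "M2"))
        es = baseline_correct(es, cfg.baseline)
        n0 = es.n_trials
        es, rejected = reject_artifacts(es, cfg.artifact_threshold)
        logger.info(
            "subject %s: %d/%d trials kept", es.subject_id, es.n_trials, n0
        )
        out.append(es)
    return out


def conventional_track(epochs: list[EpochSet]) -> dict[str, dict[str, object]]:
    """Per-subject, per-condition stimulus-locked averages."""
    return {
        es.subject_id: {
            str(c): average_evoked(es, str(c))
            for c in np.unique(es.conditions.astype(str))
        }
        for es in epochs
    }


def ride_track(
    epochs: list[EpochSet], ride_cfg: RideConfig
) -> tuple[dict[str, dict[str, object]], pd.DataFrame, list[dict]]:
    """RIDE per subject and condition: reconstructed evokeds + diagnostics."""
    evokeds: dict[str, dict[str, object]] = {}
    lat_rows, diags = [], []
    for es in epochs:
        results = run_ride_by_condition(es, ride_cfg)
        evokeds[es.subject_id] = {c: r.reconstructed for c, r in results.items()}
        for cond, r in results.items():
            diags.append(
                dict(
                    subject=es.subject_id,
                    condition=cond,
                    n_iterations=r.n_iterations,
                    converged=bool(r.converged),
                    residual_rms=r.residual_rms,
                )
            )
            for name, cl in r.clusters.items():
                for tr, lat in enumerate(cl.latencies):
                    lat_rows.append(
                        dict(subject=es.subject_id, condition=cond,
                             cluster=name, trial=tr, latency_ms=float(lat))
                    )
    return evokeds, pd.DataFrame(lat_rows), diags


def _pooled_cp_rows(table: pd.DataFrame) -> pd.DataFrame:
    pool = table[table["unit"].isin(CP_POOL)]
    agg = (
        pool.groupby(["subject", "condition", "window_start", "window_end"],
                     as_index=False)["amplitude"]
        .mean()
    )
    agg["unit"] = "centro-parietal"
    return agg


def analysis_tables(cfg, evokeds_by_track, layout):
    """Window-amplitude long tables and statistics for both tracks."""
    tables, anovas, pairwise, simple, topo = {}, {}, {}, {}, {}
    rois = sorted(layout.rois)
    for track, by_subj in evokeds_by_track.items():
        for win_name, window in cfg.windows[track].items():
            mid = long_table(by_subj, window, layout.midline, layout)
            lat = long_table(by_subj, window, rois, layout)
            tables[(track, win_name, "midline")] = mid
            tables[(track, win_name, "lateral")] = lat
            anovas[(track, win_name, "midline")] = rm_anova(
                mid, ["condition", "unit"]
            )
            anovas[(track, win_name, "lateral")] = rm_anova(
                lat, ["condition", "region", "hemisphere"]
            )
            simple[(track, win_name)] = simple_effects(lat, "condition", "unit")
            pw_input = pd.concat([mid, _pooled_cp_rows(mid)], ignore_index=True)
            pairwise[(track, win_name)] = planned_pairwise(pw_input)
            # difference topographies for the three contrasts
            frames = {}
            subjects = sorted(by_subj)
            for a, b in (("SEM", "CON"), ("SEM+SYN", "CON"), ("SEM+SYN", "SEM")):
                per_subj = [
                    difference_topography(by_subj[s][a], by_subj[s][b], window)
                    for s in subjects
                    if a in by_subj[s] and b in by_subj[s]
                ]
                if per_subj:
                    frames[f"{a}-{b}"] = pd.concat(per_subj, axis=1).mean(axis=1)
            if frames:
                topo[(track, win_name)] = pd.DataFrame(frames)
    return tables, anovas, pairwise, simple, topo


# ---------------------------------------------------------------------------
# driver


def _write_evokeds_csv(path: Path, by_subj: dict) -> None:
    rows = []
    for sid, by_cond in sorted(by_subj.items()):
        for cond, ev in sorted(by_cond.items()):
            ga = ev
            rows.append((sid, cond, ga))
    # grand averages only (per-subject full waveforms go to HDF5)
    conds = sorted({c for _, c, _ in rows})
    out = []
    for cond in conds:
        evs = [ev for _, c, ev in rows if c == cond]
        ga = grand_average(evs)
        for ch_i, ch in enumerate(ga.montage):
            for t_i, t in enumerate(ga.times):
                out.append((cond, ch, float(t), float(ga.data[ch_i, t_i])))
    pd.DataFrame(out, columns=["condition", "channel", "time_ms", "amplitude"]).to_csv(
        path, index=False
    )


def _write_evokeds_h5(path: Path, by_subj: dict) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for sid, by_cond in sorted(by_subj.items()):
            for cond, ev in sorted(by_cond.items()):
                g = f.create_group(f"{sid}/{cond}")
                g.create_dataset("data", data=ev.data.astype(np.float32))
                g.create_dataset("times", data=ev.times)
                g.attrs["n_trials"] = ev.n_trials
                g.attrs["montage"] = [str(c) for c in ev.montage]


def run_pipeline(cfg: PipelineConfig, layout: RoiLayout | None = None) -> PipelineResult:
    """Run the full chain and write the report bundle to ``cfg.out_dir``.

    On a stage failure the partial outputs are moved under
    ``out_dir/failed/`` and a :class:`StageError` naming the stage is
    raised.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    layout = layout or default_layout()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t_start = time.time()
    timings = {}
    try:
        stage = "input"
        t0 = time.time()
        epochs = load_or_simulate(cfg, layout)
        timings[stage] = time.time() - t0

        stage = "preprocess"
        t0 = time.time()
        epochs = preprocess(cfg, epochs)
        timings[stage] = time.time() - t0

        stage = "conventional"
        t0 = time.time()
        conv = conventional_track(epochs)
        _write_evokeds_csv(out / "grand_average_conventional.csv", conv)
        _write_evokeds_h5(out / "evoked_conventional.h5", conv)
        timings[stage] = time.time() - t0

        tracks = {"conventional": conv}
        if "reconstructed" in cfg.tracks:
            stage = "ride"
            t0 = time.time()
            ride_cfg = RideConfig(**cfg.ride)
            recon, latencies, diags = ride_track(epochs, ride_cfg)
            latencies.to_csv(out / "ride_latencies.csv", index=False)
            with open(out / "ride_diagnostics.json", "w") as fh:
                json.dump(diags, fh, indent=1)
            _write_evokeds_csv(out / "grand_average_reconstructed.csv", recon)
            _write_evokeds_h5(out / "evoked_reconstructed.h5", recon)
            timings[stage] = time.time() - t0
            tracks["reconstructed"] = recon

        stage = "stats"
        t0 = time.time()
        tables, anovas, pairwise, simple, topo = analysis_tables(cfg, tracks, layout)
        for (track, win, design), df in tables.items():
            df.to_csv(out / f"amplitudes_{track}_{win}_{design}.csv", index=False)
        for (track, win, design), df in anovas.items():
            df.to_csv(out / f"anova_{track}_{win}_{design}.csv", index=False)
        for (track, win), df in pairwise.items():
            df.to_csv(out / f"pairwise_{track}_{win}.csv", index=False)
        for (track, win), df in topo.items():
            df.rename_axis("channel").to_csv(out / f"topography_{track}_{win}.csv")
        timings[stage] = time.time() - t0

        stage = "manifest"
        cfg_dict = cfg.to_dict()
        manifest = dict(
            package="riderp",
            version=__version__,
            seed=cfg.seed,
            config=cfg_dict,
            config_hash=hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            numpy_version=np.__version__,
            pandas_version=pd.__version__,
            stage_seconds={k: round(v, 3) for k, v in timings.items()},
            total_seconds=round(time.time() - t_start, 3),
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in out.iterdir():
            if p != failed and p.is_file():
                shutil.move(str(p), failed / p.name)
        raise StageError(stage, exc) from exc
    return PipelineResult(
        out_dir=out,
        evokeds=tracks,
        tables=tables,
        anovas=anovas,
        pairwise=pairwise,
        simple=simple,
        topographies=topo,
        manifest=manifest,
    )
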