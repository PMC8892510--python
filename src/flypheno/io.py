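"""Readers and writers for the plain-text interchange formats.

Spike times are one-column CSV (``spike_time_s``); voltage traces are
two-column TSV (``time_s``, ``voltage_mv``); tracks are CSV (``frame``,
``time_s``, ``x_mm``, ``y_mm``); frame stacks are multi-page TIFF;
survival tables and genotype counts are CSV.  Every writer can emit a
sidecar ``<path>.params.json`` recording the generating parameters and
seed so synthetic datasets stay self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .types import FrameStack, GenotypeCounts, SpikeTrain, SurvivalCohort, Track, VoltageTrace


def write_sidecar(path: str | Path, params: Mapping[str, object]) -> Path:
    side = Path(str(path) + ".params.json")
    side.write_text(json.dumps(params, indent=2, default=str))
    return side


def write_spike_train(path: str | Path, train: SpikeTrain, params: Mapping | None = None) -> None:
    pd.DataFrame({"spike_time_s": train.times}).to_csv(path, index=False)
    if params is not None:
        write_sidecar(path, {**params, "duration_s": train.duration})


def read_spike_train(path: str | Path, duration: float | None = None) -> SpikeTrain:
    times = pd.read_csv(path)["spike_time_s"].to_numpy(dtype=float)
    if duration is None:
        side = Path(str(path) + ".params.json")
        if side.exists():
            duration = float(json.loads(side.read_text()).get("duration_s", 0) or 0)
        if not duration:
            duration = float(times[-1]) if times.size else 1.0
    return SpikeTrain(times, duration)


def write_trace(path: str | Path, trace: VoltageTrace, params: Mapping | None = None) -> None:
    pd.DataFrame({"time_s": trace.time, "voltage_mv": trace.samples}).to_csv(
        path, sep="\t", index=False
    )
    if params is not None:
        write_sidecar(
            path,
            {
                **params,
                "sampling_rate_hz": trace.sampling_rate,
                "stim_times_s": list(map(float, trace.stim_times)),
            },
        )


def read_trace(path: str | Path) -> VoltageTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(dtype=float)
    fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 10_000.0
    stim: list[float] = []
    side = Path(str(path) + ".params.json")
    if side.exists():
        meta = json.loads(side.read_text())
        fs = float(meta.get("sampling_rate_hz", fs))
        stim = meta.get("stim_times_s", [])
    return VoltageTrace(fs, df["voltage_mv"].to_numpy(dtype=float), np.asarray(stim))


def write_track(path: str | Path, track: Track, params: Mapping | None = None) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "time_s": track.frame_times,
            "x_mm": track.positions[:, 0],
            "y_mm": track.positions[:, 1],
        }
    ).to_csv(path, index=False)
    if params is not None:
        write_sidecar(path, {**params, "fps": track.fps})


def read_track(path: str | Path, fps: float | None = None) -> Track:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if fps is None:
        side = Path(str(path) + ".params.json")
        if side.exists():
            fps = float(json.loads(side.read_text()).get("fps", 0) or 0)
        if not fps:
            fps = 1.0 / np.median(np.diff(t)) if t.size > 1 else 30.0
    return Track(
        frame_times=t,
        positions=df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        fps=fps,
    )


def write_frames(path: str | Path, stack: FrameStack, params: Mapping | None = None) -> None:
    tifffile.imwrite(path, stack.frames)
    if params is not None:
        write_sidecar(
            path,
            {
                **params,
                "px_per_mm": stack.px_per_mm,
                "fps": stack.fps,
                "origin_mm": list(stack.origin_mm),
            },
        )


def read_frames(path: str | Path) -> FrameStack:
    frames = tifffile.imread(path)
    px_per_mm, fps, origin = 10.0, 30.0, (0.0, 0.0)
    side = Path(str(path) + ".params.json")
    if side.exists():
        meta = json.loads(side.read_text())
        px_per_mm = float(meta.get("px_per_mm", px_per_mm))
        fps = float(meta.get("fps", fps))
        origin = tuple(meta.get("origin_mm", origin))
    return FrameStack(frames=frames, px_per_mm=px_per_mm, fps=fps, origin_mm=origin)


def write_survival(path: str | Path, cohort: SurvivalCohort, params: Mapping | None = None) -> None:
    cohort.table.to_csv(path, index=False)
    if params is not None:
        write_sidecar(path, dict(params))


def read_survival(path: str | Path) -> SurvivalCohort:
    return SurvivalCohort(pd.read_csv(path))


def write_counts(path: str | Path, counts: GenotypeCounts, params: Mapping | None = None) -> None:
    pd.DataFrame(
        {"genotype": list(counts.counts), "count": list(counts.counts.values())}
    ).to_csv(path, index=False)
    if params is not None:
        write_sidecar(path, dict(params))


def read_counts(path: str | Path) -> GenotypeCounts:
    df = pd.read_csv(path)
    return GenotypeCounts(dict(zip(df["genotype"], df["count"].astype(int))))
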