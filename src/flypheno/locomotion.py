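"""Centroid tracking and open-field locomotor metrics.

Tracking follows the standard single-animal recipe: a per-pixel median
background over a frame sample, per-frame absolute background
subtraction, Otsu (or fixed) thresholding, largest connected component,
and an intensity-weighted centroid computed on the *unthresholded*
difference image around the component — the soft edge of the animal
carries most of the sub-pixel information.  Missing detections are
linearly interpolated across short gaps; longer gaps split the track and
metrics never bridge a split.

The four open-field metrics are total distance, percentage of active
time (frames with speed at or above a threshold), average speed over the
whole epoch (pauses included; the active-only mean is reported
alongside), and the speed correlation coefficient (SCC) — the lag-1
Pearson autocorrelation of the frame-wise speed, low for erratic or
tortuous walking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .types import FrameStack, ParameterError, Track

__all__ = [
    "TrackingParams",
    "SpeedSeries",
    "LocomotorSummary",
    "track_frames",
    "speed_series",
    "total_distance",
    "percent_active",
    "speed_correlation_coefficient",
    "locomotor_summary",
]


@dataclass(frozen=True)
class TrackingParams:
    threshold: float | str = "otsu"  # absolute-difference threshold or "otsu"
    min_area_px: int = 4
    max_gap_frames: int = 15
    bg_sample: int = 50  # frames sampled for the median background
    min_contrast: float = 20.0  # required background/foreground separation
    bbox_pad_px: int = 3


@dataclass(frozen=True)
class SpeedSeries:
    frame_times: np.ndarray
    speeds: np.ndarray  # mm/s, NaN where a step touches a missing frame
    active_threshold: float  # mm/s

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.speeds)


@dataclass(frozen=True)
class LocomotorSummary:
    total_distance_mm: float
    percent_active: float
    average_speed_mm_s: float  # distance over the full epoch, pauses included
    active_speed_mm_s: float  # mean speed over active samples only
    scc: float | None  # None when speed variance is zero
    n_missing_frames: int = 0


def _frame_centroid(
    diff: np.ndarray, thresh: float, params: TrackingParams
) -> tuple[float, float] | None:
    """Intensity-weighted centroid (row, col) of the largest component."""
    mask = diff > thresh
    if not mask.any():
        return None
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(np.argmax(sizes))
    if sizes[biggest] < params.min_area_px:
        return None
    rows, cols = np.nonzero(labels == biggest)
    pad = params.bbox_pad_px
    rlo, rhi = max(rows.min() - pad, 0), min(rows.max() + pad + 1, diff.shape[0])
    clo, chi = max(cols.min() - pad, 0), min(cols.max() + pad + 1, diff.shape[1])
    win = diff[rlo:rhi, clo:chi]
    total = win.sum()
    if total <= 0:
        return None
    rr = np.arange(rlo, rhi)
    cc = np.arange(clo, chi)
    return (
        float((win.sum(axis=1) @ rr) / total),
        float((win.sum(axis=0) @ cc) / total),
    )


def track_frames(stack: FrameStack, params: TrackingParams | None = None) -> Track:
    """Track the animal centroid through a frame stack.

    Returns a :class:`Track` in arena millimetres.  Frames with no
    component above the minimum area are missing; gaps up to
    ``max_gap_frames`` are linearly interpolated, longer gaps remain NaN
    (splitting the track for metric purposes).
    """
    params = params or TrackingParams()
    frames = stack.frames
    if frames.shape[0] < 2:
        raise ParameterError("at least two frames are required")
    idx = np.linspace(0, frames.shape[0] - 1, min(params.bg_sample, frames.shape[0]))
    background = np.median(frames[idx.astype(int)].astype(np.float32), axis=0)
    # de-ghost: an animal that barely moves survives the per-pixel median;
    # pixels far from the scene-wide median are ghost pixels and are
    # replaced by it (assumes a near-uniform arena background)
    scene = float(np.median(background))
    ghost = np.abs(background - scene) > params.min_contrast
    background[ghost] = scene

    if params.threshold == "otsu":
        sample_diff = np.abs(frames[idx.astype(int)].astype(np.float32) - background)
        peak = float(sample_diff.max())
        if peak < params.min_contrast:
            raise ParameterError(
                f"foreground contrast {peak:.1f} below minimum "
                f"{params.min_contrast:.1f}; cannot track"
            )
        thresh = float(threshold_otsu(sample_diff[sample_diff > 1.0]))
    else:
        thresh = float(params.threshold)

    centroids = np.full((frames.shape[0], 2), np.nan)
    for i in range(frames.shape[0]):
        diff = np.abs(frames[i].astype(np.float32) - background)
        rc = _frame_centroid(diff, thresh, params)
        if rc is not None:
            centroids[i] = rc
    found = ~np.isnan(centroids[:, 0])
    if not found.any():
        raise ParameterError("no detections in any frame")

    # interpolate short gaps only
    pos = stack.px_to_mm(np.nan_to_num(centroids))
    pos[~found] = np.nan
    missing = np.flatnonzero(~found)
    if missing.size:
        runs = np.split(missing, np.flatnonzero(np.diff(missing) > 1) + 1)
        frame_idx = np.arange(frames.shape[0])
        for run in runs:
            interior = run[0] > 0 and run[-1] < frames.shape[0] - 1
            if interior and run.size <= params.max_gap_frames:
                for d in range(2):
                    pos[run, d] = np.interp(
                        run, frame_idx[found], pos[found, d]
                    )
    n_missing = int(np.isnan(pos[:, 0]).sum())
    return Track(
        frame_times=np.arange(frames.shape[0]) / stack.fps,
        positions=pos,
        fps=stack.fps,
        meta={"n_missing_frames": n_missing, "threshold": thresh},
    )


def speed_series(
    track: Track, smooth_window: int = 5, active_threshold: float = 0.5
) -> SpeedSeries:
    """Frame-wise speeds in mm/s, optionally boxcar-smoothed.

    Steps touching a missing (NaN) frame yield NaN speeds and smoothing
    never bridges them.
    """
    if track.n_frames < 2:
        raise ParameterError("at least two frames are required")
    steps = np.diff(track.positions, axis=0)
    speeds = np.hypot(steps[:, 0], steps[:, 1]) * track.fps
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        valid = (~np.isnan(speeds)).astype(float)
        padded = np.nan_to_num(speeds)
        num = np.convolve(padded, kernel, mode="same")
        den = np.convolve(valid, kernel, mode="same")
        smoothed = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
        smoothed[np.isnan(speeds)] = np.nan
        speeds = smoothed
    return SpeedSeries(
        frame_times=track.frame_times[1:],
        speeds=speeds,
        active_threshold=active_threshold,
    )


def total_distance(track: Track) -> float:
    """Sum of successive displacement magnitudes (mm), skipping steps
    that touch a missing frame."""
    if track.n_frames < 2:
        raise ParameterError("at least two frames are required")
    steps = np.diff(track.positions, axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])
    return float(np.nansum(d))


def percent_active(speeds: SpeedSeries) -> float:
    """Percentage of valid speed samples at or above the active threshold."""
    valid = speeds.speeds[speeds.valid]
    if valid.size == 0:
        raise ParameterError("no valid speed samples")
    return float(100.0 * np.mean(valid >= speeds.active_threshold))


def speed_correlation_coefficient(speeds: SpeedSeries) -> float | None:
    """Lag-1 Pearson autocorrelation of the speed sequence (SCC).

    Regular walking produces smoothly varying speeds and a high SCC;
    erratic, stop-start, or tortuous walking decorrelates successive
    speeds.  Undefined (``None``) when the speed variance is zero.
    """
    s = speeds.speeds
    pair = ~np.isnan(s[:-1]) & ~np.isnan(s[1:])
    a, b = s[:-1][pair], s[1:][pair]
    if a.size < 2:
        raise ParameterError("at least three speed samples are required")
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def locomotor_summary(
    track: Track,
    smooth_window: int = 5,
    active_threshold: float = 0.5,
) -> LocomotorSummary:
    """The four open-field metrics from one consistent configuration."""
    dist = total_distance(track)
    speeds = speed_series(
        track, smooth_window=smooth_window, active_threshold=active_threshold
    )
    pct = percent_active(speeds)
    valid = speeds.speeds[speeds.valid]
    active = valid[valid >= active_threshold]
    scc = speed_correlation_coefficient(speeds)
    return LocomotorSummary(
        total_distance_mm=dist,
        percent_active=pct,
        average_speed_mm_s=dist / track.duration,
        active_speed_mm_s=float(active.mean()) if active.size else 0.0,
        scc=scc,
        n_missing_frames=int(track.meta.get("n_missing_frames", 0)),
    )
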