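"""Firing statistics and ISI⁻¹–CV₂ phase-space analysis.

The discriminator at the heart of the seizure assay pairs, for each
interior spike, the instantaneous firing rate (reciprocal of the
interspike interval, ISI⁻¹) with the instantaneous coefficient of
variation

    CV₂(i) = 2 |I(i+1) − I(i)| / (I(i+1) + I(i)),

a per-pair regularity statistic bounded in [0, 2]: rhythmic firing sits
near 0, irregular (grooming-like) firing spreads above 0.5, and seizure
burst discharges trace self-similar "loops" that repeatedly cross the
0.5 boundary as bursts start and stop.  A rule cascade over mean rate,
burst counts, and phase-space occupancy labels each recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .types import ParameterError, SpikeTrain, VoltageTrace

__all__ = [
    "PhasePortrait",
    "Burst",
    "FiringConfig",
    "FiringLabel",
    "detect_spikes",
    "interspike_intervals",
    "instantaneous_rate",
    "cv2_series",
    "mean_firing_rate",
    "phase_portrait",
    "modal_rate",
    "detect_bursts",
    "looping_index",
    "classify_firing",
]


# ---------------------------------------------------------------------------
# Basic statistics


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """First differences of the spike times (seconds); empty if < 2 spikes."""
    if train.n_spikes < 2:
        return np.empty(0)
    return np.diff(train.times)


def instantaneous_rate(train: SpikeTrain) -> np.ndarray:
    """Element-wise reciprocal of the interspike intervals (Hz)."""
    isis = interspike_intervals(train)
    return 1.0 / isis if isis.size else isis


def cv2_series(train: SpikeTrain) -> np.ndarray:
    """Pairwise CV2 for each consecutive ISI pair; empty if < 3 spikes."""
    isis = interspike_intervals(train)
    if isis.size < 2:
        return np.empty(0)
    a, b = isis[:-1], isis[1:]
    return 2.0 * np.abs(b - a) / (b + a)


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count over the full recording epoch, N / duration (Hz)."""
    return train.n_spikes / train.duration


# ---------------------------------------------------------------------------
# Phase portrait


@dataclass(frozen=True)
class PhasePortrait:
    """Ordered (ISI⁻¹, CV₂) trajectory, one point per interior spike.

    Point i pairs the instantaneous rate of the *earlier* interval I(i)
    with CV₂ computed from (I(i), I(i+1)); the ordering of points is the
    temporal trajectory.  ``duration`` is carried over from the source
    train so occupancy rates can be normalised per minute.
    """

    isi_inv: np.ndarray
    cv2: np.ndarray
    duration: float

    @property
    def n_points(self) -> int:
        return int(self.isi_inv.size)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.isi_inv, self.cv2])


def phase_portrait(train: SpikeTrain) -> PhasePortrait:
    """Build the ISI⁻¹–CV₂ trajectory of a train (N−2 points)."""
    rates = instantaneous_rate(train)
    cv2 = cv2_series(train)
    if cv2.size == 0:
        return PhasePortrait(np.empty(0), np.empty(0), train.duration)
    return PhasePortrait(rates[:-1], cv2, train.duration)


def modal_rate(portrait: PhasePortrait, bin_hz: float = 0.5) -> float | None:
    """Mode of the instantaneous firing rate, histogrammed in ``bin_hz``
    bins; returns the centre of the fullest bin (``None`` if empty)."""
    if portrait.n_points == 0:
        return None
    rates = portrait.isi_inv
    edges = np.arange(0.0, rates.max() + bin_hz, bin_hz)
    if edges.size < 2:
        return float(rates.mean())
    counts, edges = np.histogram(rates, bins=edges)
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


def looping_index(portrait: PhasePortrait, cv2_boundary: float = 0.5) -> float:
    """Phase-space looping rate: sign changes of (CV₂ − boundary) along
    the trajectory, per minute of recording.

    Seizure burst discharges repeatedly cross the boundary (low CV₂
    inside bursts, high at burst edges) giving high values; purely
    rhythmic or purely irregular firing stays on one side.
    """
    if portrait.n_points < 2:
        return 0.0
    side = np.sign(portrait.cv2 - cv2_boundary)
    side = side[side != 0]
    if side.size < 2:
        return 0.0
    transitions = int(np.sum(side[1:] != side[:-1]))
    return transitions / (portrait.duration / 60.0)


# ---------------------------------------------------------------------------
# Bursts


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int

    @property
    def intra_rate(self) -> float:
        return (self.n_spikes - 1) / (self.end - self.start)


def detect_bursts(
    train: SpikeTrain, max_intra_isi: float = 0.05, min_spikes: int = 3
) -> list[Burst]:
    """Maximal runs of consecutive ISIs <= ``max_intra_isi`` with at least
    ``min_spikes`` spikes.

    The defaults (50 ms, 3 spikes) separate >= 20 Hz burst firing from the
    ~10 Hz flight rhythm, whose 100 ms intervals never qualify.
    """
    if max_intra_isi <= 0:
        raise ParameterError("max_intra_isi must be positive")
    if min_spikes < 3:
        raise ParameterError("min_spikes must be at least 3")
    isis = interspike_intervals(train)
    if isis.size == 0:
        return []
    fast = isis <= max_intra_isi
    bursts: list[Burst] = []
    i = 0
    while i < fast.size:
        if not fast[i]:
            i += 1
            continue
        j = i
        while j < fast.size and fast[j]:
            j += 1
        n = j - i + 1  # spikes spanned by the run of fast ISIs
        if n >= min_spikes:
            bursts.append(Burst(train.times[i], train.times[j], n))
        i = j
    return bursts


# ---------------------------------------------------------------------------
# Spike detection from voltage traces


def _artifact_mask(trace: VoltageTrace, blank_ms: float) -> np.ndarray:
    """Boolean mask of samples inside stimulus-artifact blanking windows."""
    mask = np.zeros(trace.samples.size, dtype=bool)
    fs = trace.sampling_rate
    half = int(round(blank_ms / 1000.0 * fs))
    for t in trace.stim_times:
        start = int(round(t * fs))
        mask[max(start - 2, 0) : start + half + 1] = True
    return mask


def detect_spikes(
    trace: VoltageTrace,
    threshold_k: float = 4.5,
    refractory_ms: float = 5.0,
    polarity: int = 1,
    artifact_blank_ms: float = 0.5,
) -> SpikeTrain:
    """Threshold-crossing spike detection with sub-sample peak refinement.

    The threshold is ``threshold_k`` times a robust noise scale (median
    absolute deviation of the trace x 1.4826 — robust to bursts inflating
    the SD).  Crossings within the refractory period are merged into one
    event; samples inside stimulus-artifact windows are excluded.  Each
    event time is refined to the local extremum with three-point
    parabolic interpolation, so spike times are accurate well below the
    sample period.
    """
    if threshold_k <= 0:
        raise ParameterError("threshold_k must be positive")
    if refractory_ms <= 0:
        raise ParameterError("refractory period must be positive")
    x = trace.samples * (1 if polarity >= 0 else -1)
    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sigma == 0:
        return SpikeTrain(np.empty(0), trace.duration, dict(trace.meta))
    threshold = threshold_k * sigma
    above = x > threshold
    if trace.stim_times.size:
        above &= ~_artifact_mask(trace, artifact_blank_ms)
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        return SpikeTrain(np.empty(0), trace.duration, dict(trace.meta))

    fs = trace.sampling_rate
    refractory = int(round(refractory_ms / 1000.0 * fs))
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] >= refractory:
            kept.append(int(c))

    times = []
    half = max(refractory // 2, 2)
    for c in kept:
        seg = x[c : min(c + half, x.size)]
        p = c + int(np.argmax(seg))
        if 2 <= p < x.size - 2:
            # vertex of the least-squares quadratic through 5 samples
            y = x[p - 2 : p + 3]
            s0, s1, s2 = y.sum(), y @ np.arange(-2, 3), y @ (np.arange(-2, 3) ** 2)
            a = (5 * s2 - 10 * s0) / 70.0
            delta = 0.0 if a == 0 else float(np.clip(-s1 / 10.0 / (2 * a), -0.6, 0.6))
        elif 0 < p < x.size - 1:
            y0, y1, y2 = x[p - 1], x[p], x[p + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else float(
                np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
            )
        else:
            delta = 0.0
        times.append((p + delta) / fs)
    times = np.asarray(times)
    times = times[(times >= 0) & (times <= trace.duration)]
    return SpikeTrain(np.sort(times), trace.duration, dict(trace.meta))


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class FiringConfig:
    """Thresholds for the firing-pattern rule cascade.

    All values are configurable; time-like thresholds scale with the
    time unit so classification is invariant to joint rescaling.
    """

    r_quiet: float = 0.1  # Hz; below this the recording is quiescent
    b_min: int = 2  # bursts needed for the seizure label
    loop_min: float = 1.0  # boundary crossings per minute
    cv2_boundary: float = 0.5
    f_rhythm: float = 0.6  # fraction of points that must be rhythmic
    cv2_rhythm: float = 0.3
    rhythm_band: tuple[float, float] = (5.0, 20.0)  # Hz, flight rhythm
    rate_bin_hz: float = 0.5
    burst_max_intra_isi: float = 0.05  # s
    burst_min_spikes: int = 5
    burst_min_rate: float = 20.0  # Hz, intra-burst


@dataclass(frozen=True)
class FiringLabel:
    label: str  # quiescent | grooming_like | flight_like | burst_seizure
    evidence: Mapping[str, float] = field(default_factory=dict)


def classify_firing(
    train: SpikeTrain, config: FiringConfig | None = None
) -> FiringLabel:
    """Label a recording as quiescent, burst_seizure, flight_like, or
    grooming_like.

    Rule cascade: (1) mean rate below ``r_quiet`` -> quiescent;
    (2) at least ``b_min`` high-frequency bursts *and* a looping index
    above ``loop_min`` -> burst_seizure; (3) at least ``f_rhythm`` of
    phase-space points below ``cv2_rhythm`` with the modal rate inside
    the flight band -> flight_like; (4) otherwise grooming_like.
    Evidence fields are always populated.
    """
    cfg = config or FiringConfig()
    rate = mean_firing_rate(train)
    portrait = phase_portrait(train)
    bursts = [
        b
        for b in detect_bursts(
            train,
            max_intra_isi=cfg.burst_max_intra_isi,
            min_spikes=cfg.burst_min_spikes,
        )
        if b.intra_rate >= cfg.burst_min_rate
    ]
    loop = looping_index(portrait, cfg.cv2_boundary)
    if portrait.n_points:
        frac_rhythmic = float(np.mean(portrait.cv2 < cfg.cv2_rhythm))
        mode = modal_rate(portrait, cfg.rate_bin_hz)
    else:
        frac_rhythmic, mode = 0.0, None
    evidence = {
        "mean_rate_hz": rate,
        "n_bursts": len(bursts),
        "looping_per_min": loop,
        "frac_cv2_below_rhythm": frac_rhythmic,
        "modal_rate_hz": mode if mode is not None else float("nan"),
        "median_cv2": float(np.median(portrait.cv2)) if portrait.n_points else float("nan"),
    }
    if rate < cfg.r_quiet:
        return FiringLabel("quiescent", evidence)
    if len(bursts) >= cfg.b_min and loop > cfg.loop_min:
        return FiringLabel("burst_seizure", evidence)
    lo, hi = cfg.rhythm_band
    if (
        frac_rhythmic >= cfg.f_rhythm
        and mode is not None
        and lo <= mode <= hi
    ):
        return FiringLabel("flight_like", evidence)
    return FiringLabel("grooming_like", evidence)
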