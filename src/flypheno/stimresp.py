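"""Evoked-response assays.

Two stimulation paradigms share this module.  Giant-fiber (GF) assays
stimulate the descending escape neuron and read out the muscle spike:
the stimulus-to-spike latency (~1.4 ms in healthy circuits) probes the
cholinergic/electrical relay, and the following ability (% of stimuli in
a train that evoke a response) probes high-frequency reliability.
Electroconvulsive seizure (ECS) assays deliver high-frequency
stimulation across the brain and segment the stereotyped response into
an initial discharge (ID), a quiescent period (Q), and — in susceptible
flies — a delayed discharge (DD); the fraction of flies showing DD as a
function of stimulus voltage is the seizure-threshold curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohortstats import wilson_interval
from .spiketrain import detect_spikes
from .types import ParameterError, SpikeTrain, VoltageTrace

__all__ = [
    "StimulusProtocol",
    "GfResponse",
    "EcsSegmentation",
    "make_hfs_protocol",
    "detect_gf_latency",
    "following_ability",
    "segment_ecs",
    "ecs_threshold_curve",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """An evenly spaced stimulus pulse train."""

    pulse_times: np.ndarray  # s
    pulse_width_ms: float
    amplitude_v: float
    train_rate_hz: float
    train_duration_s: float


@dataclass(frozen=True)
class GfResponse:
    """Per-stimulus GF latencies (NaN where no response) and the overall
    response rate in percent."""

    latencies_ms: np.ndarray
    response_rate: float


@dataclass(frozen=True)
class EcsSegmentation:
    """ID/Q/DD windows of a post-stimulation discharge sequence.

    Absent components are ``None``; ``dd_present`` is True only when a
    delayed discharge was found inside the search window.
    """

    id_window: tuple[float, float] | None
    q_window: tuple[float, float] | None
    dd_window: tuple[float, float] | None
    dd_present: bool


def make_hfs_protocol(
    rate_hz: float = 200.0,
    duration_s: float = 2.0,
    pulse_width_ms: float = 0.1,
    amplitude_v: float = 30.0,
    start_s: float = 0.0,
) -> StimulusProtocol:
    """High-frequency stimulation train (default: 2 s of 0.1-ms pulses at
    200 Hz, the standard ECS protocol)."""
    if min(rate_hz, duration_s, pulse_width_ms, amplitude_v) <= 0:
        raise ParameterError("rate, duration, width and amplitude must be positive")
    if pulse_width_ms / 1000.0 >= 1.0 / rate_hz:
        raise ParameterError("pulse width must be shorter than the pulse period")
    n = int(round(rate_hz * duration_s))
    times = start_s + np.arange(n) / rate_hz
    return StimulusProtocol(
        pulse_times=times,
        pulse_width_ms=pulse_width_ms,
        amplitude_v=amplitude_v,
        train_rate_hz=rate_hz,
        train_duration_s=duration_s,
    )


def detect_gf_latency(
    trace: VoltageTrace,
    stim_time: float,
    search_window_ms: float = 10.0,
    artifact_blank_ms: float = 0.5,
    **detect_kwargs,
) -> float | None:
    """Stimulus-to-spike latency in ms, or ``None`` if no spike occurs.

    The first ``artifact_blank_ms`` after the stimulus is excluded (the
    shock artifact saturates the amplifier there), then the first
    detected spike within ``search_window_ms`` defines the latency.
    """
    if not 0 <= stim_time <= trace.duration:
        raise ParameterError("stim_time lies outside the trace")
    if search_window_ms <= artifact_blank_ms:
        raise ParameterError("search window must exceed the artifact blank")
    stim_times = trace.stim_times
    if stim_time not in stim_times:
        stim_times = np.sort(np.append(stim_times, stim_time))
        trace = VoltageTrace(
            trace.sampling_rate, trace.samples, stim_times, dict(trace.meta)
        )
    train = detect_spikes(trace, artifact_blank_ms=artifact_blank_ms, **detect_kwargs)
    lo = stim_time + artifact_blank_ms / 1000.0
    hi = stim_time + search_window_ms / 1000.0
    in_window = train.times[(train.times > lo) & (train.times <= hi)]
    if in_window.size == 0:
        return None
    return float((in_window[0] - stim_time) * 1000.0)


def following_ability(
    train: SpikeTrain,
    stim_times: Sequence[float],
    response_window_ms: float = 4.5,
    blank_ms: float = 0.5,
) -> GfResponse:
    """Fraction of stimuli answered by at least one spike.

    A stimulus counts as responded when a spike falls in
    ``(stim + blank, stim + window]``; each spike is consumed by at most
    one stimulus, and windows must not overlap the next stimulus.
    """
    stim = np.sort(np.asarray(list(stim_times), dtype=float))
    if stim.size == 0:
        raise ParameterError("at least one stimulus is required")
    if stim.size > 1 and response_window_ms / 1000.0 > np.min(np.diff(stim)):
        raise ParameterError("response windows overlap the next stimulus")
    window = response_window_ms / 1000.0
    blank = blank_ms / 1000.0
    latencies = np.full(stim.size, np.nan)
    spikes = train.times
    used = 0  # spikes are consumed in time order
    for i, t in enumerate(stim):
        while used < spikes.size and spikes[used] <= t + blank:
            used += 1
        if used < spikes.size and spikes[used] <= t + window:
            latencies[i] = (spikes[used] - t) * 1000.0
            used += 1
    rate = 100.0 * np.count_nonzero(~np.isnan(latencies)) / stim.size
    return GfResponse(latencies_ms=latencies, response_rate=rate)


def segment_ecs(
    train: SpikeTrain,
    stim_end: float,
    q_min: float = 2.0,
    dd_rate_min: float = 5.0,
    window: float = 60.0,
    id_gap: float = 0.5,
    dd_window_s: float = 1.0,
) -> EcsSegmentation:
    """Segment a post-stimulation spike train into ID, Q, and DD.

    ID is the spiking run starting within ``id_gap`` of the stimulation
    end (consecutive gaps < ``q_min``).  Q is the first spike-free gap of
    at least ``q_min`` after ID.  DD is the first post-Q epoch whose rate
    over a sliding ``dd_window_s`` window reaches ``dd_rate_min``;
    ``dd_present`` requires DD to begin within ``window`` seconds of the
    stimulation end.  Absent components yield ``None`` windows.
    """
    if not 0 <= stim_end <= train.duration:
        raise ParameterError("stim_end lies outside the recording")
    spikes = train.times[train.times >= stim_end]
    if spikes.size == 0:
        return EcsSegmentation(None, None, None, False)

    # --- initial discharge
    if spikes[0] - stim_end > id_gap:
        return EcsSegmentation(None, None, None, False)
    gaps = np.diff(spikes)
    run_end = 0
    while run_end < gaps.size and gaps[run_end] < q_min:
        run_end += 1
    id_window = (float(spikes[0]), float(spikes[run_end]))

    # --- quiescent period
    after = spikes[run_end + 1 :]
    if after.size == 0:
        tail_end = min(stim_end + window, train.duration)
        if tail_end - id_window[1] >= q_min:
            return EcsSegmentation(id_window, (id_window[1], tail_end), None, False)
        return EcsSegmentation(id_window, None, None, False)
    q_window = (id_window[1], float(after[0]))

    # --- delayed discharge: sliding-window rate threshold
    need = max(int(np.ceil(dd_rate_min * dd_window_s)), 2)
    dd_start_idx = None
    for i in range(after.size - need + 1):
        if after[i + need - 1] - after[i] <= dd_window_s:
            dd_start_idx = i
            break
    if dd_start_idx is None:
        return EcsSegmentation(id_window, q_window, None, False)
    dd_spikes = after[dd_start_idx:]
    dd_gaps = np.diff(dd_spikes)
    j = 0
    while j < dd_gaps.size and dd_gaps[j] < q_min:
        j += 1
    dd_window_out = (float(dd_spikes[0]), float(dd_spikes[j]))
    dd_present = dd_window_out[0] <= stim_end + window
    return EcsSegmentation(id_window, q_window, dd_window_out, dd_present)


def ecs_threshold_curve(outcomes: Iterable[tuple[float, bool]] | pd.DataFrame) -> pd.DataFrame:
    """Per-voltage fraction of flies displaying a delayed discharge.

    ``outcomes`` is an iterable of ``(voltage, dd_present)`` pairs or a
    DataFrame with ``voltage`` and ``dd_present`` columns.  Returns raw
    fractions (no smoothing, as threshold curves are conventionally
    plotted) with Wilson 95% confidence bounds, sorted by voltage:
    columns ``voltage_v``, ``n``, ``frac_dd``, ``ci_lo``, ``ci_hi``.
    """
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes[["voltage", "dd_present"]].copy()
    else:
        df = pd.DataFrame(list(outcomes), columns=["voltage", "dd_present"])
    if df.empty:
        raise ParameterError("no outcomes provided")
    rows = []
    for voltage, grp in df.groupby("voltage"):
        n = len(grp)
        k = int(grp["dd_present"].sum())
        lo, hi = wilson_interval(k, n)
        rows.append(
            {"voltage_v": float(voltage), "n": n, "frac_dd": k / n, "ci_lo": lo, "ci_hi": hi}
        )
    return pd.DataFrame(rows).sort_values("voltage_v", ignore_index=True)
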