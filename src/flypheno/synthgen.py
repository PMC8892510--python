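"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here with
controlled parameters: irregular (grooming-like) and rhythmic
(flight-like) spike trains, seizure-like burst discharges, extracellular
voltage traces with stimulus artifacts, post-stimulus electroconvulsive
discharge sequences, correlated-random-walk locomotion with activity
bouts, Weibull survival cohorts, and multinomial cross offspring with
balancer lethality.  Generators are phenomenological — they emulate the
statistics of the real assays, not membrane biophysics — and each is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .cohortstats import expected_cross_frequencies
from .types import (
    Arena,
    CrossSpec,
    FrameStack,
    GenotypeCounts,
    ParameterError,
    SpikeTrain,
    SurvivalCohort,
    Track,
    VoltageTrace,
)

__all__ = [
    "gen_poisson_train",
    "gen_rhythmic_train",
    "gen_burst_train",
    "gen_ecs_train",
    "gen_voltage_trace",
    "gen_walk",
    "render_frames",
    "gen_survival_cohort",
    "gen_cross_offspring",
    "weibull_scale_from_median",
    "weibull_median_from_survival_at",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Spike trains


def gen_poisson_train(rate: float, duration: float, seed=None, meta=None) -> SpikeTrain:
    """Homogeneous Poisson spike train on ``[0, duration]``.

    Models irregular, grooming-like motor-unit firing: exponential
    interspike intervals, so the pairwise CV2 statistic is uniform on
    [0, 2] with mean 1.
    """
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = _rng(seed)
    if rate == 0:
        return SpikeTrain(np.empty(0), duration, meta or {})
    # draw a safe surplus of ISIs, then truncate to the recording window
    n_guess = int(rate * duration + 6 * math.sqrt(rate * duration) + 10)
    isis = rng.exponential(1.0 / rate, size=n_guess)
    times = np.cumsum(isis)
    while times.size and times[-1] < duration:
        extra = rng.exponential(1.0 / rate, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration]
    return SpikeTrain(times, duration, meta or {})


def gen_rhythmic_train(
    rate: float,
    jitter_cv: float,
    duration: float,
    seed=None,
    meta=None,
) -> SpikeTrain:
    """Rhythmic renewal train (flight-like firing, e.g. ~10 Hz).

    Interspike intervals are gamma-distributed with mean ``1/rate`` and
    coefficient of variation ``jitter_cv``; ``jitter_cv=0`` gives a
    perfectly regular clock.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if jitter_cv < 0:
        raise ParameterError("jitter_cv must be non-negative")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = _rng(seed)
    mean_isi = 1.0 / rate
    n_guess = int(duration * rate + 6 * math.sqrt(duration * rate + 1) + 10)
    if jitter_cv == 0:
        isis = np.full(n_guess, mean_isi)
    else:
        shape = 1.0 / jitter_cv**2
        isis = rng.gamma(shape, mean_isi / shape, size=n_guess)
    times = np.cumsum(isis)
    times = times[times < duration]
    return SpikeTrain(times, duration, meta or {})


def gen_burst_train(
    burst_onset_rate: float,
    intra_rate: float = 50.0,
    spikes_per_burst: int = 10,
    duration: float = 60.0,
    intra_jitter_cv: float = 0.05,
    seed=None,
    meta=None,
) -> SpikeTrain:
    """Seizure-like high-frequency burst discharges.

    Burst onsets follow a Poisson process thinned so consecutive bursts
    are separated by at least three intra-burst intervals beyond the
    burst span (bursts in the real recordings are stereotypic and well
    separated, so detection is well-posed).  Within a burst, spikes are
    near-rhythmic at ``intra_rate``.

    Ground-truth burst onsets are stored in ``meta['burst_onsets']``.
    """
    if intra_rate <= burst_onset_rate:
        raise ParameterError("intra_rate must exceed burst_onset_rate")
    if spikes_per_burst < 3:
        raise ParameterError("spikes_per_burst must be at least 3")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    intra_isi = 1.0 / intra_rate
    span = (spikes_per_burst - 1) * intra_isi
    gap = 3.0 * intra_isi
    if burst_onset_rate > 0 and burst_onset_rate * (span + gap) >= 1.0:
        raise ParameterError(
            "requested burst rate cannot accommodate non-overlapping bursts"
        )
    rng = _rng(seed)
    meta = dict(meta or {})
    if burst_onset_rate == 0:
        meta["burst_onsets"] = np.empty(0)
        return SpikeTrain(np.empty(0), duration, meta)
    candidates = gen_poisson_train(burst_onset_rate, duration, rng).times
    onsets = []
    last_end = -np.inf
    for t in candidates:
        if t >= last_end + gap and t + span < duration:
            onsets.append(t)
            last_end = t + span
    spikes = []
    for onset in onsets:
        if intra_jitter_cv == 0:
            isis = np.full(spikes_per_burst - 1, intra_isi)
        else:
            shape = 1.0 / intra_jitter_cv**2
            isis = rng.gamma(shape, intra_isi / shape, size=spikes_per_burst - 1)
        spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
    times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    times = times[times < duration]
    meta["burst_onsets"] = np.asarray(onsets)
    return SpikeTrain(times, duration, meta)


def gen_ecs_train(
    dd_present: bool,
    stim_end: float = 2.0,
    id_duration: float = 2.5,
    id_rate: float = 40.0,
    q_duration: float = 5.0,
    dd_duration: float = 8.0,
    dd_rate: float = 30.0,
    duration: float = 60.0,
    jitter_cv: float = 0.3,
    seed=None,
    meta=None,
) -> SpikeTrain:
    """Post-stimulus electroconvulsive discharge sequence.

    After high-frequency brain stimulation ending at ``stim_end`` the
    stereotypic seizure sequence is an initial discharge (ID), a
    quiescent period (Q), and — above threshold — a delayed discharge
    (DD).  When ``dd_present`` is False only the ID is generated.
    """
    if stim_end < 0 or stim_end + id_duration + q_duration + dd_duration > duration:
        raise ParameterError("discharge sequence does not fit in the recording")
    rng = _rng(seed)
    segments = [
        gen_rhythmic_train(id_rate, jitter_cv, id_duration, rng).times + stim_end
    ]
    if dd_present:
        dd_start = stim_end + id_duration + q_duration
        segments.append(
            gen_rhythmic_train(dd_rate, jitter_cv, dd_duration, rng).times + dd_start
        )
    times = np.sort(np.concatenate(segments))
    meta = dict(meta or {})
    meta.setdefault("dd_present", bool(dd_present))
    return SpikeTrain(times, duration, meta)


# ---------------------------------------------------------------------------
# Voltage traces


def gen_voltage_trace(
    train: SpikeTrain,
    fs: float = 10_000.0,
    spike_amp: float = 40.0,
    spike_width_ms: float = 1.0,
    noise_sd: float = 2.0,
    stim_times: Sequence[float] = (),
    artifact_amp: float = 500.0,
    artifact_width_ms: float = 0.3,
    seed=None,
) -> VoltageTrace:
    """Render a spike train as an extracellular voltage trace (mV).

    A biphasic template (one sine cycle of ``spike_width_ms``) is placed
    with its *positive peak* at each spike time on top of Gaussian noise;
    each stimulus time receives a rectangular saturating artifact so that
    latency detection must blank the artifact window, as in real
    recordings.  If two spikes fall closer than the template width the
    trace is labelled ``meta['overlap_warning']``.
    """
    if fs < 1000:
        raise ParameterError("fs must be at least 1000 Hz")
    if spike_width_ms <= 2.0 and fs < 5000:
        raise ParameterError("fs must be >= 5000 Hz for spike widths <= 2 ms")
    if noise_sd > 0 and spike_amp <= 5 * noise_sd:
        raise ParameterError("spike_amp must exceed 5x noise_sd for detectability")
    rng = _rng(seed)
    n = int(round(train.duration * fs))
    samples = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    width = spike_width_ms / 1000.0
    peak_offset = width / 4.0  # positive lobe peak sits at the spike time
    for t in train.times:
        # evaluate the template on the exact sample grid so the rendered
        # peak is not quantised to the sample period
        t_start = t - peak_offset
        lo = max(int(math.ceil(t_start * fs)), 0)
        hi = min(int(math.floor((t_start + width) * fs)) + 1, n)
        if lo < hi:
            phase = (np.arange(lo, hi) / fs - t_start) / width
            samples[lo:hi] += spike_amp * np.sin(2 * np.pi * phase)

    art_n = max(int(round(artifact_width_ms / 1000.0 * fs)), 1)
    stim_times = np.asarray(list(stim_times), dtype=float)
    for t in stim_times:
        start = int(round(t * fs))
        samples[start : min(start + art_n, n)] = artifact_amp

    meta = dict(train.meta)
    if train.n_spikes >= 2 and np.min(np.diff(train.times)) < width:
        meta["overlap_warning"] = True
    return VoltageTrace(
        sampling_rate=fs, samples=samples, stim_times=stim_times, meta=meta
    )


# ---------------------------------------------------------------------------
# Locomotion


def gen_walk(
    duration: float = 180.0,
    fps: float = 30.0,
    move_speed_mean: float = 8.0,
    move_speed_sd: float = 2.0,
    turn_kappa: float = 8.0,
    p_move_to_pause: float = 1 / 60,
    p_pause_to_move: float = 1 / 60,
    arena: Arena | None = None,
    start_state: str | None = None,
    seed=None,
    meta=None,
) -> Track:
    """Two-state (move/pause) correlated random walk in an arena.

    Per frame, a Markov chain switches between a paused state and a
    moving state; while moving, the heading performs a wrapped-normal
    random walk with concentration ``turn_kappa`` and the step length is
    drawn from a truncated normal speed distribution.  The arena boundary
    is reflective.  Ground truth is stored in ``meta``: the boolean move
    state per frame (``state_move``) and the stationary move-state
    occupancy implied by the transition probabilities
    (``move_occupancy``).
    """
    if not (0 <= p_move_to_pause <= 1 and 0 <= p_pause_to_move <= 1):
        raise ParameterError("transition probabilities must be in [0, 1]")
    if fps < 10:
        raise ParameterError("fps must be at least 10")
    if turn_kappa <= 0:
        raise ParameterError("turn_kappa must be positive")
    arena = arena or Arena()
    rng = _rng(seed)
    n = int(round(duration * fps))
    step_scale = move_speed_mean / fps
    limit = arena.radius_mm if arena.kind == "circular" else min(
        arena.width_mm, arena.height_mm
    ) / 2
    if step_scale >= limit:
        raise ParameterError("arena too small for a single step")

    # Markov state sequence
    states = np.empty(n, dtype=bool)  # True = moving
    if start_state is None:
        denom = p_move_to_pause + p_pause_to_move
        p_move0 = 0.5 if denom == 0 else p_pause_to_move / denom
        states[0] = rng.random() < p_move0
    else:
        states[0] = start_state == "move"
    u = rng.random(n)
    for i in range(1, n):
        if states[i - 1]:
            states[i] = u[i] >= p_move_to_pause
        else:
            states[i] = u[i] < p_pause_to_move

    heading = rng.uniform(0, 2 * np.pi)
    turn_sd = 1.0 / math.sqrt(turn_kappa)
    pos = np.zeros((n, 2))
    pos[0] = (0.0, 0.0)
    for i in range(1, n):
        pos[i] = pos[i - 1]
        if not states[i]:
            continue
        heading = (heading + rng.normal(0.0, turn_sd)) % (2 * np.pi)
        speed = max(rng.normal(move_speed_mean, move_speed_sd), 0.0)
        step = speed / fps
        cand = pos[i - 1] + step * np.array([math.cos(heading), math.sin(heading)])
        if not arena.contains(cand)[0]:
            # reflect: head back toward the interior with the same step
            heading = (heading + np.pi) % (2 * np.pi)
            cand = pos[i - 1] + step * np.array(
                [math.cos(heading), math.sin(heading)]
            )
            if not arena.contains(cand)[0]:
                cand = pos[i - 1]
        pos[i] = cand

    denom = p_move_to_pause + p_pause_to_move
    meta = dict(meta or {})
    meta.setdefault("state_move", states)
    meta.setdefault(
        "move_occupancy", 0.5 if denom == 0 else p_pause_to_move / denom
    )
    return Track(
        frame_times=np.arange(n) / fps, positions=pos, fps=fps, arena=arena, meta=meta
    )


def render_frames(
    track: Track,
    px_per_mm: float = 10.0,
    fly_radius_px: float = 5.0,
    fly_intensity: float = 60.0,
    bg_intensity: float = 200.0,
    noise_sd: float = 4.0,
    margin_mm: float = 2.0,
    seed=None,
) -> FrameStack:
    """Render a track as a grayscale frame stack (ground-truth video).

    Each frame shows one soft-edged disc (dark on bright background by
    default; swap the intensities for the opposite contrast) centred at
    the track position, plus Gaussian pixel noise.  Frames whose track
    position is NaN contain background only, emulating a missed
    detection.
    """
    if abs(fly_intensity - bg_intensity) < 5 * noise_sd:
        raise ParameterError("fly/background contrast must be >= 5x noise_sd")
    arena = track.arena
    if arena.kind == "circular":
        half_w = half_h = arena.radius_mm + margin_mm
    else:
        half_w = arena.width_mm / 2 + margin_mm
        half_h = arena.height_mm / 2 + margin_mm
    width = int(math.ceil(2 * half_w * px_per_mm))
    height = int(math.ceil(2 * half_h * px_per_mm))
    if 2 * fly_radius_px >= min(width, height):
        raise ParameterError("fly does not fit inside the rendered field")
    origin = (-half_w, -half_h)

    finite = np.isfinite(track.positions).all(axis=1)
    cols = (track.positions[:, 0] - origin[0]) * px_per_mm
    rows = (track.positions[:, 1] - origin[1]) * px_per_mm
    pad = fly_radius_px + 1
    if np.any(
        finite
        & ((cols < pad) | (cols > width - pad) | (rows < pad) | (rows > height - pad))
    ):
        raise ParameterError("track extends outside the rendered field")

    rng = _rng(seed)
    n = track.n_frames
    frames = np.empty((n, height, width), dtype=np.uint8)
    r_int = int(math.ceil(fly_radius_px)) + 2
    for i in range(n):
        img = rng.normal(bg_intensity, noise_sd, size=(height, width))
        if finite[i]:
            r0, c0 = rows[i], cols[i]
            rlo, rhi = int(r0) - r_int, int(r0) + r_int + 1
            clo, chi = int(c0) - r_int, int(c0) + r_int + 1
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            dist = np.hypot(rr - r0, cc - c0)
            # soft edge: linear ramp one pixel wide, approximates pixel coverage
            coverage = np.clip(fly_radius_px + 0.5 - dist, 0.0, 1.0)
            img[rlo:rhi, clo:chi] += (fly_intensity - bg_intensity) * coverage
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return FrameStack(
        frames=frames,
        px_per_mm=px_per_mm,
        fps=track.fps,
        origin_mm=origin,
        meta={"fly_radius_px": fly_radius_px},
    )


# ---------------------------------------------------------------------------
# Survival and genetics


def weibull_scale_from_median(median_days: float, shape: float) -> float:
    """Weibull scale lambda such that the distribution median equals
    ``median_days`` for the given shape k: lambda = median / ln(2)^(1/k)."""
    if median_days <= 0 or shape <= 0:
        raise ParameterError("median_days and shape must be positive")
    return median_days / math.log(2.0) ** (1.0 / shape)


def weibull_median_from_survival_at(
    t: float, survival: float, shape: float
) -> float:
    """Median of the Weibull (given shape) whose survival at time ``t``
    equals ``survival``.  Used to calibrate cohorts to a reported
    day-``t`` survival fraction."""
    if not 0 < survival < 1:
        raise ParameterError("survival must be in (0, 1)")
    scale = t / (-math.log(survival)) ** (1.0 / shape)
    return scale * math.log(2.0) ** (1.0 / shape)


def gen_survival_cohort(
    n: int,
    median_days: float,
    shape: float = 5.0,
    max_follow_up_days: float = np.inf,
    genotype: str = "unknown",
    diet: str = "unknown",
    seed=None,
) -> SurvivalCohort:
    """Weibull survival cohort calibrated to a true median.

    The shape parameter controls how aging-like the hazard is (shape 1 is
    memoryless/exponential; larger shapes give the sigmoidal survival
    curves typical of fly life-span assays).  Times beyond
    ``max_follow_up_days`` are right-censored there.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    scale = weibull_scale_from_median(median_days, shape)
    rng = _rng(seed)
    t = scale * rng.weibull(shape, size=n)
    event = (t <= max_follow_up_days).astype(int)
    t = np.minimum(t, max_follow_up_days)
    return SurvivalCohort.from_arrays(t, event, genotype=genotype, diet=diet)


def gen_cross_offspring(cross: CrossSpec, n: int, seed=None) -> GenotypeCounts:
    """Multinomial offspring draw over the viable Mendelian classes.

    Class probabilities come from :func:`expected_cross_frequencies`
    (balancer homozygotes removed, viability coefficients applied and
    renormalised), so ``n`` is the number of *viable* offspring scored.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    probs = expected_cross_frequencies(cross)
    rng = _rng(seed)
    labels = list(probs)
    draws = rng.multinomial(n, [probs[k] for k in labels])
    return GenotypeCounts(dict(zip(labels, (int(d) for d in draws))))
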