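"""Core domain containers shared across the toolkit.

Everything downstream operates on a handful of small, validated value
objects: spike trains, extracellular voltage traces, centroid tracks,
rendered frame stacks, survival cohorts, and genetic cross bookkeeping.
They are deliberately thin wrappers over numpy arrays and pandas frames —
the analysis lives in the functional modules, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """A generator or analysis routine was given an invalid parameter."""


#: Alleles recognised in cross specifications.  ``TM6B`` is the third-
#: chromosome balancer (homozygous-inviable); ``Df`` is a deficiency
#: removing the endogenous fly PNPO locus (sgll); ``sgll+`` is the intact
#: fly chromosome; the ``h*`` alleles are human PNPO knock-ins.
ALLELE_REGISTRY = frozenset(
    {"hWT", "hR116Q", "hD33V", "hR95H", "sgll+", "TM6B", "Df"}
)

#: Alleles whose homozygotes are never viable (balancer chromosomes).
BALANCER_ALLELES = frozenset({"TM6B"})


def genotype_label(a: str, b: str) -> str:
    """Canonical ``allele/allele`` label, allele order-independent."""
    x, y = sorted((a, b))
    return f"{x}/{y}"


def is_homozygote(label: str) -> bool:
    a, _, b = label.partition("/")
    return bool(b) and a == b


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times from a single recording.

    Parameters
    ----------
    times:
        Spike times in seconds, strictly increasing, within
        ``[0, duration]``.
    duration:
        Recording duration in seconds (> 0).
    meta:
        Free-form labels (genotype, diet, condition, ...).
    """

    times: np.ndarray
    duration: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if times.ndim != 1:
            raise ParameterError("spike times must be a 1-D sequence")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ParameterError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration:
                raise ParameterError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Translate all spike times by ``offset`` (duration grows to fit)."""
        return SpikeTrain(
            self.times + offset, self.duration + max(offset, 0.0), dict(self.meta)
        )


@dataclass(frozen=True)
class VoltageTrace:
    """An extracellular voltage recording (e.g. DLM flight muscle).

    ``samples`` are in mV at ``sampling_rate`` Hz; ``stim_times`` marks
    stimulus deliveries (seconds) whose artifacts must be blanked during
    spike detection.
    """

    sampling_rate: float
    samples: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate < 1000:
            raise ParameterError("sampling_rate must be at least 1000 Hz")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(
            self, "stim_times", np.sort(np.asarray(self.stim_times, dtype=float))
        )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class Arena:
    """Open-field arena geometry.

    ``kind`` is ``"circular"`` (uses ``radius_mm``) or ``"rectangular"``
    (uses ``width_mm`` × ``height_mm``, origin at the centre).
    """

    kind: str = "circular"
    radius_mm: float = 20.0
    width_mm: float = 40.0
    height_mm: float = 40.0

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.kind == "circular":
            return np.hypot(xy[:, 0], xy[:, 1]) <= self.radius_mm - margin
        hw, hh = self.width_mm / 2 - margin, self.height_mm / 2 - margin
        return (np.abs(xy[:, 0]) <= hw) & (np.abs(xy[:, 1]) <= hh)


@dataclass(frozen=True)
class Track:
    """Timestamped 2-D centroid trajectory in arena coordinates (mm).

    ``positions`` may contain NaN rows for frames with no detection;
    locomotor metrics skip steps that touch a missing frame.
    """

    frame_times: np.ndarray
    positions: np.ndarray
    fps: float
    arena: Arena = field(default_factory=Arena)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ParameterError("positions must be an (n, 2) array")
        if ft.size != pos.shape[0]:
            raise ParameterError("frame_times and positions length mismatch")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class FrameStack:
    """Grayscale video frames (uint8) plus the geometry needed to map
    pixel coordinates back to arena millimetres."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    px_per_mm: float
    fps: float
    origin_mm: tuple[float, float] = (0.0, 0.0)  # mm position of pixel (0, 0)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ParameterError("px_per_mm must be positive")
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ParameterError("frames must be (n, h, w)")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def px_to_mm(self, rc: np.ndarray) -> np.ndarray:
        """Convert (row, col) pixel coordinates to (x, y) mm."""
        rc = np.atleast_2d(np.asarray(rc, dtype=float))
        x = self.origin_mm[0] + rc[:, 1] / self.px_per_mm
        y = self.origin_mm[1] + rc[:, 0] / self.px_per_mm
        return np.column_stack([x, y])


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-individual time-to-event records with right censoring.

    ``table`` columns: ``id``, ``genotype``, ``diet``, ``day`` (>= 0) and
    ``event`` (1 = died, 0 = censored at ``day``).
    """

    table: pd.DataFrame

    REQUIRED = ("id", "genotype", "diet", "day", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ParameterError(f"survival table missing columns: {missing}")
        if (self.table["day"] < 0).any():
            raise ParameterError("event/censoring days must be non-negative")
        if not self.table["event"].isin((0, 1)).all():
            raise ParameterError("event must be 0 (censored) or 1 (died)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @staticmethod
    def from_arrays(
        days: Sequence[float],
        events: Sequence[int],
        genotype: str = "unknown",
        diet: str = "unknown",
    ) -> "SurvivalCohort":
        days = np.asarray(days, dtype=float)
        return SurvivalCohort(
            pd.DataFrame(
                {
                    "id": np.arange(days.size),
                    "genotype": genotype,
                    "diet": diet,
                    "day": days,
                    "event": np.asarray(events, dtype=int),
                }
            )
        )


@dataclass(frozen=True)
class CrossSpec:
    """A two-parent genetic cross with balancer/viability bookkeeping.

    Each parent carries exactly two alleles from :data:`ALLELE_REGISTRY`.
    Offspring genotypes homozygous for a balancer are inviable; further
    per-genotype viability coefficients in [0, 1] scale each class before
    renormalisation.
    """

    parent_a: tuple[str, str]
    parent_b: tuple[str, str]
    viability: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele in (*self.parent_a, *self.parent_b):
            if allele not in ALLELE_REGISTRY:
                raise ParameterError(f"unknown allele {allele!r}")
        for label, v in self.viability.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(
                    f"viability for {label} must be in [0, 1], got {v}"
                )


@dataclass(frozen=True)
class GenotypeCounts:
    """Offspring tallies keyed by canonical genotype label."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for label, c in self.counts.items():
            if c < 0:
                raise ParameterError(f"negative count for {label}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def __getitem__(self, label: str) -> int:
        return int(self.counts.get(label, 0))
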