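"""Core domain containers for ECG quality assessment.

All time points are seconds relative to the start of the parent recording;
inter-beat (RR) intervals are milliseconds.  Conversions happen only at the
boundaries of these types, never inside algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CardioQCError(Exception):
    """Base class for domain errors raised by cardioqc."""


class DataError(CardioQCError):
    """Malformed or physically impossible input data."""


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-channel ECG waveform.

    Parameters
    ----------
    samples : array of float
        Amplitudes in device units (typically mV).
    fs : float
        Sampling frequency in Hz, strictly positive.
    channel_label : str
        Free-text channel name, e.g. ``"ECG"`` or a device lead label.
    start_time : float or None
        Optional absolute start timestamp in seconds.  All internal
        processing uses times relative to the first sample.
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "ECG"
    start_time: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise DataError(f"sampling frequency must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise DataError("ECGRecord holds a single channel (1-D array)")
        if samples.size < 2:
            raise DataError("ECGRecord needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise DataError("ECG samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (time of the last sample)."""
        return (self.samples.size - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample time points in seconds relative to the record start."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatAnnotation:
    """Ordered beat (R peak) time points.

    ``source`` distinguishes a manually verified ground truth
    (``"reference"``) from an algorithmic annotation (``"detected"``).
    """

    times: np.ndarray
    source: str = "detected"
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.source not in ("reference", "detected"):
            raise DataError(f"source must be 'reference' or 'detected', got {self.source!r}")
        if times.ndim != 1:
            raise DataError("beat times must be a 1-D array")
        if times.size and not np.all(np.isfinite(times)):
            raise DataError("beat times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DataError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RRSequence:
    """An ordered sequence of inter-beat intervals in milliseconds.

    Intervals must be positive; no physiological-plausibility bounds are
    enforced because real devices emit artifactual intervals, and those are
    exactly what downstream alignment is meant to find.
    """

    intervals: np.ndarray

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if intervals.ndim != 1:
            raise DataError("RR intervals must be a 1-D array")
        if intervals.size and (not np.all(np.isfinite(intervals)) or np.any(intervals <= 0)):
            raise DataError("RR intervals must be finite and positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class Phase:
    """A labelled half-open time span ``[start, end)`` in seconds."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"phase {self.label!r}: start must be < end")

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered, pairwise-disjoint experimental phases."""

    phases: tuple[Phase, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        for prev, cur in zip(phases, phases[1:]):
            if cur.start < prev.end:
                raise DataError(
                    f"phases {prev.label!r} and {cur.label!r} overlap or are out of order"
                )

    def __iter__(self):
        return iter(self.phases)

    def __len__(self) -> int:
        return len(self.phases)
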