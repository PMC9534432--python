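"""Synthetic ECG, beat trains, noise and annotation corruptions.

Everything here is a pure function of its specification, seed included:
rerunning with the same spec is bit-identical.  The generator is the test
substrate for the quality metrics — it produces controllable PQRST
morphology with exact ground-truth R times, the classic ambulatory noise
categories (broadband, baseline wander, powerline, EMG bursts), and
annotation corruptions with a log that serves as ground truth for
alignment-based error classification.

What it does *not* emulate: arrhythmias, ectopy, conduction abnormalities,
electrode-motion transients or any dynamical heart model.  Cycles are sums
of five Gaussians (P, Q, R, S, T) stretched with the local cycle length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import BeatAnnotation, DataError, ECGRecord, RRSequence

__all__ = [
    "RRGenSpec",
    "ECGGenSpec",
    "NoiseSpec",
    "PerturbationLog",
    "DEFAULT_WAVES",
    "gen_rr",
    "gen_ecg",
    "add_noise",
    "perturb_annotation",
]

RR_CLIP_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class RRGenSpec:
    """Beat-train specification.

    ``mean_rr`` (ms) sets the heart rate, ``sdnn`` (ms) the beat-to-beat
    Gaussian variability, and a sinusoid of ``resp_depth`` ms at
    ``resp_freq`` Hz emulates respiratory sinus arrhythmia.  Intervals are
    clipped to 300–2000 ms (30–200 bpm) with a warning counting clips.
    """

    n_beats: int = 60
    mean_rr: float = 800.0
    sdnn: float = 40.0
    resp_freq: float = 0.25
    resp_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be > 0")
        if self.sdnn < 0 or self.resp_depth < 0:
            raise ValueError("sdnn and resp_depth must be >= 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


# (amplitude mV, width ms, offset ms from R) at the nominal cycle length;
# Q and S at -35/+30 ms with ~10 ms widths give a ~100 ms QRS complex, so
# the default QRS notch is exercised by default morphology
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 25.0, -180.0),
    "Q": (-0.10, 10.0, -35.0),
    "R": (1.00, 12.0, 0.0),
    "S": (-0.15, 10.0, 30.0),
    "T": (0.30, 60.0, 220.0),
}


@dataclass(frozen=True)
class ECGGenSpec:
    """Waveform rendering specification.

    ``wave_params`` maps wave name to (amplitude mV, width ms, offset ms
    relative to the R peak) at the ``nominal_rr`` cycle length; offsets and
    widths stretch linearly with the local RR interval so the P–T complex
    follows cycle length.  The R amplitude must dominate all other waves.
    """

    fs: float = 256.0
    wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    baseline: float = 0.0
    nominal_rr: float = 800.0
    lead_in: float = 0.5  # seconds of flat margin before the first R peak

    def __post_init__(self) -> None:
        amp_r = abs(self.wave_params["R"][0])
        for name, (amp, width, _) in self.wave_params.items():
            if width <= 0:
                raise ValueError(f"wave {name}: width must be > 0")
            if name != "R" and abs(amp) >= amp_r:
                raise ValueError("R amplitude must dominate all other waves")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise specification.

    kind: ``white`` (broadband Gaussian), ``baseline_wander`` (slow
    sinusoid, default 0.33 Hz), ``powerline`` (default 50 Hz, the European
    mains frequency) or ``emg_burst`` (Gaussian gated on/off in blocks with
    duty cycle ``burst_duty``).  ``amplitude`` is in the record's units
    (the Gaussian kinds use it as the standard deviation).
    """

    kind: str = "white"
    amplitude: float = 0.1
    freq: float | None = None
    burst_duty: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "baseline_wander", "powerline", "emg_burst"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.burst_duty <= 1:
            raise ValueError("burst_duty must be in [0, 1]")


@dataclass(frozen=True)
class PerturbationLog:
    """Ground truth of an annotation corruption."""

    inserted: tuple[float, ...]  # times of added beats (s)
    deleted: tuple[float, ...]  # times of removed beats (s)
    shifted: tuple[tuple[float, float], ...]  # (original, new) time pairs (s)


def gen_rr(spec: RRGenSpec) -> RRSequence:
    """Generate a beat-to-beat interval sequence.

    Each interval is ``mean_rr + resp_depth*sin(2π·resp_freq·t) + N(0, sdnn)``
    where ``t`` is the cumulative time at the beat, then clipped to the
    physiological range.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.sdnn, size=spec.n_beats) if spec.sdnn > 0 else np.zeros(
        spec.n_beats
    )
    intervals = np.empty(spec.n_beats)
    t = 0.0
    for i in range(spec.n_beats):
        rr = spec.mean_rr + spec.resp_depth * np.sin(2 * np.pi * spec.resp_freq * t) + noise[i]
        intervals[i] = rr
        t += max(rr, RR_CLIP_MS[0]) / 1000.0
    clipped = np.clip(intervals, *RR_CLIP_MS)
    n_clips = int(np.sum(clipped != intervals))
    if n_clips:
        warnings.warn(f"clipped {n_clips} RR intervals to {RR_CLIP_MS} ms", stacklevel=2)
    return RRSequence(intervals=clipped)


def gen_ecg(rr: RRSequence, spec: ECGGenSpec | None = None) -> tuple[ECGRecord, BeatAnnotation]:
    """Render an RR sequence as a waveform with exact R-time annotations.

    Each beat is a sum of five Gaussians placed relative to its R time.
    Waves before the R peak (P, Q) stretch with the preceding interval,
    waves after it (S, T) with the following one, so morphology warps
    consistently with cycle length.  The returned annotation holds the
    exact R-Gaussian centre times and is the ground truth for detection
    and quality tests.
    """
    spec = spec or ECGGenSpec()
    if len(rr) == 0:
        raise DataError("cannot render an empty RR sequence")
    r_times = spec.lead_in + np.concatenate(([0.0], np.cumsum(rr.intervals) / 1000.0))
    duration = r_times[-1] + spec.lead_in
    n = int(round(duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    samples = np.full(n, spec.baseline, dtype=float)
    intervals_s = rr.intervals / 1000.0
    for k, r_t in enumerate(r_times):
        prev_rr = intervals_s[k - 1] if k > 0 else intervals_s[0]
        next_rr = intervals_s[k] if k < intervals_s.size else intervals_s[-1]
        for amp, width_ms, offset_ms in spec.wave_params.values():
            stretch = (prev_rr if offset_ms < 0 else next_rr) * 1000.0 / spec.nominal_rr
            center = r_t + offset_ms / 1000.0 * stretch
            sigma = width_ms / 1000.0 * stretch
            i0 = max(0, int(np.floor((center - 5 * sigma) * spec.fs)))
            i1 = min(n, int(np.ceil((center + 5 * sigma) * spec.fs)) + 1)
            if i1 > i0:
                samples[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - center) / sigma) ** 2)
    record = ECGRecord(samples=samples, fs=spec.fs, channel_label="synthetic ECG")
    beats = BeatAnnotation(times=r_times, source="reference", label="synthetic")
    return record, beats


def add_noise(record: ECGRecord, spec: NoiseSpec) -> ECGRecord:
    """Add one noise component; zero amplitude returns the input unchanged."""
    if spec.amplitude == 0:
        return record
    rng = np.random.default_rng(spec.seed)
    t = record.times
    if spec.kind == "white":
        noise = spec.amplitude * rng.standard_normal(record.n_samples)
    elif spec.kind == "baseline_wander":
        freq = spec.freq if spec.freq is not None else 0.33
        phase = rng.uniform(0, 2 * np.pi)
        noise = spec.amplitude * np.sin(2 * np.pi * freq * t + phase)
    elif spec.kind == "powerline":
        freq = spec.freq if spec.freq is not None else 50.0
        phase = rng.uniform(0, 2 * np.pi)
        noise = spec.amplitude * np.sin(2 * np.pi * freq * t + phase)
    else:  # emg_burst
        block = max(1, int(round(0.5 * record.fs)))
        n_blocks = int(np.ceil(record.n_samples / block))
        gate = np.repeat(rng.random(n_blocks) < spec.burst_duty, block)[: record.n_samples]
        noise = spec.amplitude * rng.standard_normal(record.n_samples) * gate
    return ECGRecord(
        samples=record.samples + noise,
        fs=record.fs,
        channel_label=record.channel_label,
        start_time=record.start_time,
    )


def perturb_annotation(
    beats: BeatAnnotation,
    n_insert: int = 0,
    n_delete: int = 0,
    n_shift: int = 0,
    shift_ms: float = 80.0,
    min_separation: int = 10,
    seed: int = 0,
    edge_margin: int | None = None,
) -> tuple[BeatAnnotation, PerturbationLog]:
    """Corrupt a beat annotation with logged, well-separated events.

    Insertions add a beat at the midpoint of an interval (splitting one RR
    into two equal halves); deletions remove a beat (merging two RRs);
    shifts move a beat by ±``shift_ms``.  Event sites are interior beats at
    pairwise index distance >= ``min_separation`` and at least
    ``edge_margin`` beats from either end (default: ``min_separation``), so
    alignment-based error classification sees each event embedded in
    matched context — local alignment trims sequence ends, and an event too
    close to an end cannot be attributed reliably.  An infeasible request
    raises :class:`~cardioqc.types.DataError`.
    """
    n_events = n_insert + n_delete + n_shift
    rng = np.random.default_rng(seed)
    margin = max(0, min_separation if edge_margin is None else edge_margin)
    candidates = np.arange(margin, len(beats) - margin - 1)
    if n_events == 0:
        return beats, PerturbationLog((), (), ())
    # greedy seeded site selection with the separation constraint
    order = rng.permutation(candidates)
    sites: list[int] = []
    for idx in order:
        if all(abs(idx - s) >= min_separation for s in sites):
            sites.append(int(idx))
        if len(sites) == n_events:
            break
    if len(sites) < n_events:
        raise DataError(
            f"cannot place {n_events} events {min_separation} beats apart in {len(beats)} beats"
        )
    roles = ["insert"] * n_insert + ["delete"] * n_delete + ["shift"] * n_shift
    rng.shuffle(roles)

    times = list(beats.times)
    inserted: list[float] = []
    deleted: list[float] = []
    shifted: list[tuple[float, float]] = []
    # apply in descending site order so earlier indices stay valid
    for site, role in sorted(zip(sites, roles), reverse=True):
        if role == "insert":
            new_t = (times[site] + times[site + 1]) / 2.0
            times.insert(site + 1, new_t)
            inserted.append(new_t)
        elif role == "delete":
            deleted.append(times.pop(site))
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            new_t = times[site] + sign * shift_ms / 1000.0
            shifted.append((times[site], new_t))
            times[site] = new_t
    perturbed = BeatAnnotation(
        times=np.asarray(times), source="detected", label=f"{beats.label}+perturbed"
    )
    return perturbed, PerturbationLog(
        inserted=tuple(sorted(inserted)),
        deleted=tuple(sorted(deleted)),
        shifted=tuple(sorted(shifted)),
    )
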