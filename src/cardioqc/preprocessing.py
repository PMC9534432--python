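"""Bandpass filtering and R-peak refinement.

The 3–20 Hz band keeps the QRS complex while suppressing baseline wander
below and muscle/powerline noise above it, which is what energy-based beat
detectors want to see.  Filtering is zero-phase (forward-backward) so that
beat timing is not biased by filter group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .types import BeatAnnotation, DataError, ECGRecord

__all__ = ["FilterSpec", "bandpass", "refine_peaks", "detect_beats_fallback"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (defaults: 3–20 Hz, order 4)."""

    low_cut: float = 3.0
    high_cut: float = 20.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise DataError(f"need 0 < low_cut < high_cut, got {self.low_cut}/{self.high_cut}")
        if self.high_cut >= fs / 2:
            raise DataError(
                f"high_cut {self.high_cut} Hz must lie below the Nyquist frequency {fs / 2} Hz"
            )


def bandpass(record: ECGRecord, spec: FilterSpec | None = None) -> ECGRecord:
    """Zero-phase Butterworth bandpass; same length and sampling frequency.

    Applied forward and backward (``sosfiltfilt``), so the effective
    attenuation is twice the design order and the phase response is zero —
    the filter does not move R peaks.
    """
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    sos = sps.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=record.fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, record.samples)
    return ECGRecord(
        samples=filtered,
        fs=record.fs,
        channel_label=record.channel_label,
        start_time=record.start_time,
    )


def refine_peaks(
    record: ECGRecord,
    coarse: BeatAnnotation,
    window_ms: float = 40.0,
    upsample_factor: int = 8,
) -> BeatAnnotation:
    """Move each coarse beat to the spline-interpolated local extremum.

    Within ±``window_ms``/2 of each coarse beat the signal is cubic-spline
    upsampled by ``upsample_factor`` and the beat is moved to the extremum of
    larger absolute excursion from the recording's median baseline (lead
    polarity differs between devices, so a fixed-sign maximum would be wrong).  Windows
    reaching beyond the record are clamped, never an error.  Beats may not
    cross: a refinement that would break monotonicity falls back to the
    coarse location.
    """
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    half = window_ms / 2000.0  # seconds
    fs = record.fs
    times = record.times
    baseline = float(np.median(record.samples))  # robust record-level baseline
    refined = np.array(coarse.times, dtype=float)
    for k, t in enumerate(coarse.times):
        if not 0 <= t <= record.duration:
            raise DataError(f"coarse beat at {t} s lies outside the record")
        lo = max(0.0, t - half)
        hi = min(record.duration, t + half)
        i0 = max(0, int(np.floor(lo * fs)) - 2)  # margin for spline support
        i1 = min(record.n_samples, int(np.ceil(hi * fs)) + 3)
        if i1 - i0 < 4:
            continue  # too few samples for a cubic spline; keep coarse time
        spline = CubicSpline(times[i0:i1], record.samples[i0:i1])
        grid = np.arange(lo, hi + 0.5 / (fs * upsample_factor), 1.0 / (fs * upsample_factor))
        grid = grid[(grid >= lo) & (grid <= hi)]
        values = spline(grid)
        # polarity from the dominant excursion off the recording's baseline
        excursion = values - baseline
        peak = np.argmax(np.abs(excursion))
        refined[k] = grid[peak]
    # enforce monotonicity: revert any beat that crossed its neighbour
    for k in range(1, refined.size):
        if refined[k] <= refined[k - 1]:
            refined[k] = coarse.times[k]
    if refined.size > 1 and not np.all(np.diff(refined) > 0):
        raise DataError("refinement could not preserve beat order")
    return BeatAnnotation(times=refined, source=coarse.source, label=coarse.label)


def detect_beats_fallback(record: ECGRecord, refractory_ms: float = 250.0) -> BeatAnnotation:
    """Simple energy-threshold beat detector.

    This is plumbing so pipelines can run end-to-end on synthetic data.  It
    is *not* a validated QRS detector and is no substitute for one: use a
    published detector's annotations for real analyses.

    The bandpassed signal is squared and smoothed over 100 ms; envelope
    peaks above 20 % of the maximum, at least ``refractory_ms`` apart, are
    reported as beats.  Squaring makes the detector polarity-invariant.
    """
    if record.duration < 5.0:
        raise DataError("fallback detection needs at least 5 s of signal")
    filtered = bandpass(record).samples
    if np.ptp(filtered) < 1e-12 * max(1.0, np.abs(record.samples).max()):
        warnings.warn("flat signal: no beats detected", stacklevel=2)
        return BeatAnnotation(times=np.empty(0), source="detected", label="fallback")
    energy = filtered**2
    win = max(1, int(round(0.1 * record.fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")
    peaks, _ = sps.find_peaks(
        envelope,
        height=0.2 * envelope.max(),
        distance=max(1, int(round(refractory_ms / 1000.0 * record.fs))),
    )
    return BeatAnnotation(times=peaks / record.fs, source="detected", label="fallback")
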