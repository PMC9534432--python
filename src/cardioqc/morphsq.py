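"""morphSQ — a local morphological noise-to-signal index for ECG.

Each beat is rated by comparing the cardiac cycles around it against their
median cycle after time-normalization, on a percentage-like scale where 0 is
a perfectly repeating morphology and larger values mean more noise.

For a beat with ``k`` full cycles of context (``k+1`` R peaks, the rated
peak in the middle):

1.  Cycle boundaries are the midpoints between consecutive R peaks.
2.  Each cycle is cut at its R peak into a left segment (P-wave side,
    boundary→R) and a right segment (T-wave side, R→boundary).
3.  Left segments are linearly rescaled onto [-1, 0] and right segments
    onto [0, 1], then sampled by linear interpolation on a shared grid, so
    cycles of different length become directly comparable.
4.  The median across segments at every grid point is the template; its
    peak-to-peak amplitude is ``a``.
5.  Differences ``d`` between each segment and the template are weighted by
    a per-cycle Gaussian weight (cycles nearer the rated beat count more)
    with weights forced to 0 inside a ±50 ms notch around every R peak, so
    respiration-driven R-amplitude modulation is not scored as noise.
6.  The index is ``(1/a) * sum(w * d**2) / sum(w)``.

The index is >= 0, invariant under uniform time dilation, and scales
linearly with the signal amplitude (the squared differences are normalized
by ``a``, not ``a**2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .types import BeatAnnotation, CardioQCError, DataError, ECGRecord, PhaseSegmentation

__all__ = [
    "MorphSQParams",
    "CycleWindow",
    "RescaledSegments",
    "MorphSQResult",
    "MorphSQISummary",
    "WindowUnavailableError",
    "DegenerateSignalError",
    "build_cycle_window",
    "rescale_segments",
    "median_template",
    "weight_matrix",
    "morphsq_at_beat",
    "morphsq_series",
    "summarize_morphsqi",
]


class WindowUnavailableError(CardioQCError):
    """The beat lacks the k/2 cycles of context needed on one side."""


class DegenerateSignalError(DataError):
    """The median cycle is flat (amplitude 0); the index is undefined."""


@dataclass(frozen=True)
class MorphSQParams:
    """Tuning parameters of the morphological quality index.

    k : even number of full cardiac cycles per window (default 8).
    grid_step : rescaled-time increment of the comparison grid
        (default 0.002, i.e. 501 points per half-cycle).
    qrs_notch_ms : total width of the zero-weight region centred on each
        R peak (default 100 ms, the physiological QRS duration).
    weight_span : half-range of the Gaussian weight coordinate; R-peak
        indices 0..k map linearly onto [-span, +span] (default 2).
    sufficiency_cutoff : threshold below which a beat counts as having
        sufficient quality (default 0.10).
    """

    k: int = 8
    grid_step: float = 0.002
    qrs_notch_ms: float = 100.0
    weight_span: float = 2.0
    sufficiency_cutoff: float = 0.10

    def __post_init__(self) -> None:
        if self.k < 2 or self.k % 2:
            raise ValueError(f"k must be even and >= 2, got {self.k}")
        if not 0 < self.grid_step <= 1:
            raise ValueError("grid_step must be in (0, 1]")
        if self.qrs_notch_ms < 0:
            raise ValueError("qrs_notch_ms must be >= 0")
        if self.sufficiency_cutoff <= 0:
            raise ValueError("sufficiency_cutoff must be > 0")

    @property
    def n_half(self) -> int:
        """Number of grid intervals per half-cycle."""
        return int(round(1.0 / self.grid_step))


@dataclass(frozen=True)
class CycleWindow:
    """k+1 R-peak times with the rated peak at index k/2, plus cycle bounds.

    ``midpoints[j]`` is the boundary between cycles j and j+1, i.e. the end
    of cycle j and the start of cycle j+1 — the two coincide by construction.
    """

    r_times: np.ndarray  # k+1 strictly increasing R-peak times (s)
    midpoints: np.ndarray  # k boundaries between consecutive R peaks (s)

    @property
    def k(self) -> int:
        return self.r_times.size - 1

    def left_bounds(self, i: int) -> tuple[float, float]:
        """Start/end of left segment i (i = 1..k): midpoint(i-1, i) → R_i."""
        return float(self.midpoints[i - 1]), float(self.r_times[i])

    def right_bounds(self, i: int) -> tuple[float, float]:
        """Start/end of right segment i (i = 0..k-1): R_i → midpoint(i, i+1)."""
        return float(self.r_times[i]), float(self.midpoints[i])


@dataclass(frozen=True)
class RescaledSegments:
    """Time-normalized cycle segments sampled on the shared query grid.

    ``left_values[i-1]`` holds left segment i on the grid [-1, 0];
    ``right_values[i]`` holds right segment i on [0, 1].  Durations are the
    original segment lengths in seconds (needed to convert the QRS notch
    from milliseconds back into grid units per segment).
    """

    grid_left: np.ndarray  # n_half+1 points from -1 to 0
    grid_right: np.ndarray  # n_half+1 points from 0 to 1
    left_values: np.ndarray  # (k, n_half+1)
    right_values: np.ndarray  # (k, n_half+1)
    left_durations: np.ndarray  # (k,) seconds
    right_durations: np.ndarray  # (k,) seconds


@dataclass(frozen=True)
class MorphSQResult:
    """Per-beat quality values plus the beats that could not be rated."""

    times: np.ndarray  # beat times with a defined value (s)
    values: np.ndarray  # morphSQ value per beat, >= 0
    undefined_beats: np.ndarray  # beat times lacking a full window (s)


@dataclass(frozen=True)
class MorphSQISummary:
    """Summary of morphSQ values: mean, SD and the sufficient-quality rate."""

    mean: float
    sd: float
    proportion_sufficient: float
    n_beats: int
    per_phase: dict[str, "MorphSQISummary"] = field(default_factory=dict)


def build_cycle_window(beats: BeatAnnotation, center_index: int, k: int) -> CycleWindow:
    """Select the k+1 R peaks around ``center_index`` and their midpoints."""
    half = k // 2
    if center_index - half < 0 or center_index + half >= len(beats):
        raise WindowUnavailableError(
            f"beat {center_index} lacks {half} beats of context on each side"
        )
    r = np.asarray(beats.times[center_index - half : center_index + half + 1], dtype=float)
    mid = (r[:-1] + r[1:]) / 2.0
    return CycleWindow(r_times=r, midpoints=mid)


def rescale_segments(
    record: ECGRecord, window: CycleWindow, grid_step: float = 0.002
) -> RescaledSegments:
    """Time-normalize all cycle segments onto the shared query grid.

    Left segment i maps its start midpoint to -1 and R_i to 0; right
    segment i maps R_i to 0 and its end midpoint to +1.  Values come from
    linear interpolation of the raw samples, so the segment value at the
    R-peak end equals the interpolated signal at that R peak for every
    segment anchored there.
    """
    k = window.k
    if window.midpoints[0] < 0 or window.midpoints[-1] > record.duration:
        raise WindowUnavailableError("cycle window extends beyond the record")
    n_half = int(round(1.0 / grid_step))
    grid_left = np.linspace(-1.0, 0.0, n_half + 1)
    grid_right = np.linspace(0.0, 1.0, n_half + 1)
    sample_times = record.times
    left_values = np.empty((k, n_half + 1))
    right_values = np.empty((k, n_half + 1))
    left_durations = np.empty(k)
    right_durations = np.empty(k)
    for i in range(1, k + 1):
        s, r_t = window.left_bounds(i)
        left_durations[i - 1] = r_t - s
        t = r_t + grid_left * (r_t - s)  # q=-1 → s, q=0 → R_i
        left_values[i - 1] = np.interp(t, sample_times, record.samples)
    for i in range(k):
        r_t, e = window.right_bounds(i)
        right_durations[i] = e - r_t
        t = r_t + grid_right * (e - r_t)  # q=0 → R_i, q=1 → e
        right_values[i] = np.interp(t, sample_times, record.samples)
    return RescaledSegments(
        grid_left=grid_left,
        grid_right=grid_right,
        left_values=left_values,
        right_values=right_values,
        left_durations=left_durations,
        right_durations=right_durations,
    )


def median_template(segments: RescaledSegments) -> tuple[np.ndarray, np.ndarray, float]:
    """Median cycle across the overlaid segments and its amplitude.

    Returns ``(template_left, template_right, amplitude)`` where the two
    template halves share the grid of the segments.  At grid point 0, which
    both a left and a right segment cover per cycle, the median is taken
    over all 2k anchor values and written into both halves, so the template
    is a single function on [-1, 1].  Amplitude is max - min of that
    function; a flat template raises :class:`DegenerateSignalError` because
    the index normalizes by the amplitude.
    """
    left = np.median(segments.left_values, axis=0)
    right = np.median(segments.right_values, axis=0)
    center = np.median(
        np.concatenate([segments.left_values[:, -1], segments.right_values[:, 0]])
    )
    template_left = left.copy()
    template_right = right.copy()
    template_left[-1] = center
    template_right[0] = center
    full = np.concatenate([template_left, template_right[1:]])
    amplitude = float(full.max() - full.min())
    if amplitude == 0.0:
        raise DegenerateSignalError("flat median cycle: morphSQ is undefined")
    return template_left, template_right, amplitude


def weight_matrix(
    window: CycleWindow, segments: RescaledSegments, params: MorphSQParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(segment, grid point) weights: Gaussian locality × QRS notch.

    Each segment carries the standard-normal density φ(x_i) of its parent
    R peak, where peak indices 0..k map linearly onto
    [-weight_span, +weight_span] (the rated central peak maps to 0).  The
    weight is constant within a segment: locality is a property of the
    cycle, not of the position inside it.  On top of that, grid points
    whose back-transformed time lies within ±qrs_notch_ms/2 of the
    segment's R peak are set to 0; because segments are time-warped, the
    notch width in grid units differs per segment.
    """
    k = window.k
    x = (np.arange(k + 1) - k / 2) * (2.0 * params.weight_span / k)
    phi = norm.pdf(x)
    notch_half_s = params.qrs_notch_ms / 2000.0

    # left segment i is anchored at R_i (i = 1..k); |q| * duration is the
    # time distance from the R peak for grid coordinate q in [-1, 0]
    w_left = np.repeat(phi[1:, None], segments.grid_left.size, axis=1)
    dist_left = np.abs(segments.grid_left)[None, :] * segments.left_durations[:, None]
    w_left = np.where(dist_left <= notch_half_s, 0.0, w_left)

    w_right = np.repeat(phi[:-1, None], segments.grid_right.size, axis=1)
    dist_right = np.abs(segments.grid_right)[None, :] * segments.right_durations[:, None]
    w_right = np.where(dist_right <= notch_half_s, 0.0, w_right)
    return w_left, w_right


def morphsq_at_beat(
    record: ECGRecord,
    beats: BeatAnnotation,
    center_index: int,
    params: MorphSQParams | None = None,
) -> float:
    """The morphological noise-to-signal value of one beat.

    ``(1/a) * sum(w * d**2) / sum(w)`` over all (segment, grid point)
    pairs, where ``d`` is observation minus median template and ``a`` the
    template's peak-to-peak amplitude.  Deterministic and >= 0.
    """
    params = params or MorphSQParams()
    window = build_cycle_window(beats, center_index, params.k)
    segments = rescale_segments(record, window, params.grid_step)
    template_left, template_right, amplitude = median_template(segments)
    w_left, w_right = weight_matrix(window, segments, params)
    d_left = segments.left_values - template_left[None, :]
    d_right = segments.right_values - template_right[None, :]
    num = float(np.sum(w_left * d_left**2) + np.sum(w_right * d_right**2))
    den = float(np.sum(w_left) + np.sum(w_right))
    if den == 0.0:
        raise DegenerateSignalError("all weights are zero (notch covers every grid point)")
    return num / (amplitude * den)


def morphsq_series(
    record: ECGRecord, beats: BeatAnnotation, params: MorphSQParams | None = None
) -> MorphSQResult:
    """morphSQ for every beat with full context (sliding-window evaluation).

    Beats within k/2 of either end of the annotation, or whose window
    reaches past the record, are reported in ``undefined_beats`` rather
    than computed on a shrunken window — the statistic keeps one
    definition for all beats.
    """
    params = params or MorphSQParams()
    if len(beats) < params.k + 1:
        raise DataError(f"need at least k+1 = {params.k + 1} beats, got {len(beats)}")
    times, values, undefined = [], [], []
    for idx in range(len(beats)):
        try:
            value = morphsq_at_beat(record, beats, idx, params)
        except WindowUnavailableError:
            undefined.append(beats.times[idx])
            continue
        times.append(beats.times[idx])
        values.append(value)
    return MorphSQResult(
        times=np.asarray(times), values=np.asarray(values), undefined_beats=np.asarray(undefined)
    )


def _summary_of(values: np.ndarray, cutoff: float) -> MorphSQISummary:
    if values.size == 1:
        warnings.warn("single morphSQ value: SD reported as 0", stacklevel=3)
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return MorphSQISummary(
        mean=float(np.mean(values)),
        sd=sd,
        proportion_sufficient=float(np.mean(values < cutoff)),
        n_beats=int(values.size),
    )


def summarize_morphsqi(
    result: MorphSQResult,
    cutoff: float = 0.10,
    phases: PhaseSegmentation | None = None,
) -> MorphSQISummary:
    """Mean, SD (n-1 denominator) and rate of morphSQ < cutoff.

    The sufficiency comparison is strict (< cutoff).  With a phase
    segmentation, a per-phase breakdown is attached; phases containing no
    rated beats are absent from it rather than reported as zero.
    """
    if result.values.size == 0:
        raise DataError("no morphSQ values to summarize")
    summary = _summary_of(result.values, cutoff)
    if phases is None:
        return summary
    per_phase: dict[str, MorphSQISummary] = {}
    for phase in phases:
        mask = (result.times >= phase.start) & (result.times < phase.end)
        if mask.any():
            per_phase[phase.label] = _summary_of(result.values[mask], cutoff)
    return MorphSQISummary(
        mean=summary.mean,
        sd=summary.sd,
        proportion_sufficient=summary.proportion_sufficient,
        n_beats=summary.n_beats,
        per_phase=per_phase,
    )
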