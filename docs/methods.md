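# Methods

This note documents the models implemented by `cardioqc`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical and design decisions a maintainer should know about.

## Morphological noise-to-signal index (morphSQ)

### Procedure

For a beat with at least k/2 annotated beats on each side (k = 8 by
default, even):

1. Take the k+1 R-peak times around the rated beat and the midpoints
   between consecutive peaks; midpoints delimit k full cardiac cycles, and
   the end of cycle i is exactly the start of cycle i+1.
2. Cut each cycle at its R peak: the left segment (boundary → R, contains
   the P wave) is affinely mapped onto rescaled time [−1, 0], the right
   segment (R → boundary, contains the T wave) onto [0, 1].
3. Sample every segment by linear interpolation of the raw waveform on a
   shared grid with step 0.002 (501 points per half).
4. The template is the pointwise median across segments; at grid point 0,
   covered by a left and a right segment of every cycle, the median is
   taken over all 2k anchor values and written into both template halves,
   so the template is one function on [−1, 1]. Its amplitude is
   a = max − min; a flat template raises a degenerate-signal error because
   the index divides by a.
5. Each (segment, grid point) difference d from the template receives a
   weight ω: the standard-normal density φ(x) of the segment's parent
   R-peak index mapped linearly onto [−2, 2] (the rated peak at 0, so the
   central cycle weighs φ(0) ≈ 0.399 and the outermost φ(2) ≈ 0.054),
   zeroed wherever the grid point's back-transformed time lies within
   ±50 ms of that segment's R peak (the QRS notch, 100 ms total).
6. morphSQ = (1/a) · Σ ω d² / Σ ω.

### Interpretation and properties

* morphSQ ≥ 0, and 0 exactly when every weighted difference vanishes: a
  noiseless, morphology-stable recording scores 0 regardless of heart-rate
  changes (time rescaling absorbs cycle-length variation).
* The QRS notch means amplitude modulation confined to the R peak —
  typically respiration — does not register. This is deliberate: the index
  targets noise, not physiological beat-to-beat amplitude variation.
* The squared differences are normalized by the template amplitude to the
  *first* power, so the index carries the signal's amplitude unit and
  scaling the waveform by c scales morphSQ by c. This is the definition as
  published; an amplitude-invariant variant (pre-normalizing the window so
  a = 1) can be had by dividing the input by the template amplitude first,
  but is intentionally not the default.
* Weighting is per cycle (a function of the cycle's position in the
  window), not a continuous function of rescaled time; the notch then acts
  within each cycle. Where the weighting convention was ambiguous, the
  per-cycle reading was chosen because locality is a property of cycles.
* Beats without a full k-cycle window (the first and last k/2, or windows
  reaching past the record) are reported as undefined, never computed on
  shrunken windows — one definition for every reported value.

The recording-level summary (morphSQI) is the mean, the SD (n−1
denominator; a single value reports SD 0 with a warning) and the fraction
of beats with morphSQ strictly below the 0.10 sufficiency cutoff, overall
and per experimental phase (phases with no rated beats are omitted rather
than reported as zero).

### Numerical notes

* Everything is linear interpolation on the raw samples; no smoothing.
* The notch boundary is inclusive (ω = 0 at exactly ±50 ms).
* A clean *sampled* ECG scores exactly 0 only when the cycle length is an
  integer number of samples (e.g. 1000 ms at 256 Hz); otherwise cycles are
  sampled at different phases and linear-interpolation residuals leave
  values of order 1e-5 · amplitude. Tests of the exact-zero property use
  commensurate cycles; this is a property of sampling, not of the index.

## Beat-detection evaluation

Matching is greedy globally-nearest one-to-one within ±50 ms: candidate
(reference, detected) pairs are ordered by |Δt| (ties toward the earlier
reference beat, then the earlier detection) and accepted greedily. When
inter-beat spacing exceeds twice the tolerance — always true for
physiological rhythms against a 50 ms window — this equals maximum-
cardinality bipartite matching (asserted against an assignment-problem
oracle in the tests). Metrics follow the standard definitions: PPV =
TP/(TP+FP), FNR = FN/(TP+FN), sensitivity = 1 − FNR, F1 the harmonic mean
of PPV and sensitivity, misclassification rate (FP+FN)/reference-beats.
Ratios with zero denominators are reported as absent (None) with a warning,
never as 0 — "no detections" is not "all detections wrong". F1 bands count
recordings in [0, 0.90), [0.90, 0.99] (inclusive) and (0.99, 1].

Per-phase evaluation assigns a matched pair to the phase containing its
reference time (half-open [start, end) spans), an unmatched reference beat
to the phase containing it, and an unmatched detection to the phase
containing its own time; matching itself is computed once globally so a
pair can never straddle a phase boundary inconsistently.

## RR-interval alignment

The scoring scheme is fixed by the method being implemented: reward
s(a,b) = max(0, 1 − (a−b)²/1000) for pairing two intervals (ms), −1.0 for a
deletion (query gap, missed beat), +0.9 for an insertion (reference gap,
spurious beat). The matrix is O(mn) with zero first row/column and a floor
at 0; traceback starts at the global maximum (ties broken toward the
smallest reference then query index) and prefers diagonal over deletion
over insertion when predecessors tie, so pairings beat gaps.

Column kinds use the 50 ms evaluation tolerance, independent of the reward:
a diagonal column is a *match* iff |a−b| ≤ 50 ms, else a *mismatch*.

### Error classification

Insertions count as FP, deletions as FN. Misplaced beats are found by
scanning each maximal run of non-match columns left to right while
accumulating the reference-side and query-side interval sums; when the sums
agree within the tolerance the group since the last closure is complete:

* a compensated group containing a gap column is the signature of that
  insertion or deletion (one interval split into two, or two merged into
  one) and is already counted as FP/FN;
* a compensated group of pure mismatches is one misplaced beat — a shifted
  beat produces exactly two adjacent wrong intervals with equal sums;
* mismatch columns left uncompensated when the run ends count one event
  each.

No closed-form rule for misplaced counting exists in the method's source
material; this sum-compensation rule is the package's interpretation,
chosen so that the three elementary corruptions (split, merge, shift)
classify as exactly one FP, one FN and one misplaced event respectively.

### The positive insertion reward and its consequences

Rewarding insertions (+0.9) rather than penalizing them makes a skipped
query interval almost as valuable as a perfect match (+1.0). This has
real, documented consequences:

* trailing (and, via a zero-scored start cell, leading) query intervals
  beyond the matched region are absorbed as rewarded insertion columns;
* a lone mismatched pair with no context becomes an insertion, not a
  mismatch;
* wherever skipping a stretch of the reference (possible only at the ends
  of the local span) saves more than 0.1 per trimmed matched column — for
  example when annotation errors cluster near a sequence end — the optimal
  alignment trims that stretch and its error events become unattributable;
* a shifted beat can be re-expressed as deletion + diagonal + insertion
  when a neighbouring interval difference happens to fall within the
  reward's support around the shift (|Δ − shift| < ~31.6 ms), converting
  one misplaced event into one FP plus one FN.

Planted-error recovery is therefore *exact* only when errors are embedded
in enough matched context (≳30 beats from sequence ends) and the interval
series is variable enough that wrong pairings score below 0.9 yet not so
variable that neighbour differences reach the shift magnitude. The test
suite demonstrates exact recovery on a monotone heart-rate-ramp series (12
ms/beat), where both conditions hold by construction, and treats recovery
on stationary noisy series as the approximate behaviour it is. The scheme
is implemented as published; none of these properties are "fixed".

Sequences up to tens of thousands of intervals use the full matrix; a size
guard refuses allocations beyond 2·10⁸ cells.

## Synthetic data

The generator exists to exercise every analysis with known ground truth.

* **Beat trains**: interval = mean_rr + resp_depth·sin(2π·resp_freq·t) +
  N(0, sdnn), clipped to 300–2000 ms with a warning. Defaults emulate a
  resting adult: mean_rr 800 ms (75 bpm), sdnn 40 ms (typical short-term
  resting SDNN), resp_depth 30 ms at 0.25 Hz (respiratory sinus arrhythmia
  at 15 breaths/min). The CLI's activity profiles (rest / walk / uphill)
  set mean heart rate to 93.6 / 103.3 / 153.7 bpm and breathing to 14.5 /
  24.1 / 27.1 cycles per minute, with variability decreasing as intensity
  rises.
* **Waveforms**: each beat is a sum of five Gaussians (P, Q, R, S, T) whose
  offsets and widths stretch linearly with the local RR interval; the
  default QRS (Q at −35 ms to S at +30 ms) spans ~100 ms so the default
  notch is exercised. The annotation holds the exact R-Gaussian centres.
  This is a morphology generator, not a dynamical heart model: no
  arrhythmias, ectopy, electrode-motion transients or waveform drift — so
  passing tests say nothing about such pathologies on real data.
* **Noise**: additive white Gaussian, baseline wander (0.33 Hz sinusoid),
  powerline (50 Hz, the mains frequency where the emulated devices are
  used), and EMG bursts (Gaussian gated in 0.5 s blocks by a duty cycle).
* **Corruptions**: insertions at interval midpoints, deletions, ±shift_ms
  shifts, at sites pairwise ≥ min_separation beats apart and ≥ edge_margin
  beats from the ends, all logged as ground truth.

All generators are pure functions of their specification including the
seed; reruns are bit-identical.

## Files and formats

EDF (16-bit) carries waveforms; the built-in reader/writer covers plain
single-data-stream EDF as exported by wearable recorders (EDF+ annotation
streams are not interpreted) and round-trips samples to one quantization
step. Beats and RR intervals travel as one-column CSV/TSV (beat units —
sample indices, seconds or milliseconds — are declared by header or flag;
there is no value-based guessing, because a silent misparse is worse than a
required flag). Duplicate beat rows collapse with a warning; Polar HRM-style
section headers in RR files are tolerated. All internal times are seconds;
intervals are milliseconds; conversion happens only at type boundaries.

## Preprocessing

The detection-support bandpass is a 4th-order Butterworth (3–20 Hz) applied
forward-backward: zero phase, so filtering never biases beat timing; the
order and band are configurable. R-peak refinement cubic-spline-upsamples
(8×) a ±20 ms window around each coarse beat and moves it to the extremum
of larger absolute excursion from the recording's median baseline —
polarity-agnostic, since lead polarity differs between devices. Windows
clamp at record edges; a refinement that would reorder beats falls back to
the coarse location. The bundled energy-threshold beat detector (squared
bandpassed signal, 100 ms smoothing, 20 % peak threshold, 250 ms
refractory) exists so pipelines run end-to-end on synthetic data; it is not
a validated QRS detector and real analyses should consume annotations from
one.

## Known limitations

* morphSQ requires accurate, verified beat annotations; it is sensitive to
  beat misplacement (a misplaced R peak distorts the rescaling anchors).
* The alignment's insertion reward makes long gap-padded optima possible on
  pathological queries (see above); error counts on low-variability or
  heavily corrupted series should be read as approximate.
* The per-phase assignment of detected-only beats (by their own time) is a
  convention; other conventions move boundary beats between phases.
* The EDF writer emits single-channel (or equal-rate multi-channel) files
  with a 16-bit quantization floor.
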