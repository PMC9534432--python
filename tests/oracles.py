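"""Independent brute-force oracles, deliberately naive.

These re-derive expected values by enumeration or plain-loop arithmetic and
share no code path with the package implementations they check.
"""

from __future__ import annotations

import math


def brute_force_local_best(a, b, deletion_penalty=1.0, insertion_reward=0.9, scale=1000.0):
    """Best local-alignment score by exhaustive path enumeration.

    Explores every monotone lattice path through interior cells (row and
    column 0 act as zero-valued anchors), scoring diagonal steps with the
    capped quadratic reward, vertical steps with -deletion_penalty and
    horizontal steps with +insertion_reward.  Every path prefix is a valid
    local alignment, so the running maximum over all prefixes (and the
    empty alignment, 0) is the optimum.  Exponential; use only for tiny
    sequences.
    """
    m, n = len(a), len(b)
    best = 0.0

    def step_reward(i, j):  # 1-based interval indices
        return max(0.0, 1.0 - (a[i - 1] - b[j - 1]) ** 2 / scale)

    def walk(i, j, score):
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            walk(i + 1, j + 1, score + step_reward(i + 1, j + 1))
        if i < m and j >= 1:  # vertical move may not run along column 0
            walk(i + 1, j, score - deletion_penalty)
        if j < n and i >= 1:  # horizontal move may not run along row 0
            walk(i, j + 1, score + insertion_reward)

    for i0 in range(m + 1):
        for j0 in range(n + 1):
            walk(i0, j0, 0.0)
    return best


def naive_morphsq(samples, fs, beat_times, center_index, k, grid_step,
                  qrs_notch_ms=100.0, weight_span=2.0):
    """Plain-loop morphological quality value for one beat.

    Re-implements the whole procedure — cycle boundaries at midpoints,
    per-half time rescaling, manual linear interpolation, list-sort
    medians, per-cycle Gaussian weights with a time-domain QRS notch and
    the weighted, amplitude-normalized sum of squared differences — without
    numpy, as an arithmetic cross-check.
    """
    half = k // 2
    r = [beat_times[center_index + d] for d in range(-half, half + 1)]
    mid = [(r[i] + r[i + 1]) / 2.0 for i in range(k)]
    n_half = round(1.0 / grid_step)
    grid_left = [-1.0 + t / n_half for t in range(n_half + 1)]
    grid_right = [t / n_half for t in range(n_half + 1)]

    def interp(t):
        x = t * fs
        i = int(math.floor(x))
        if i < 0:
            return samples[0]
        if i >= len(samples) - 1:
            return samples[-1]
        frac = x - i
        return samples[i] * (1.0 - frac) + samples[i + 1] * frac

    left_vals, left_dur = [], []
    for i in range(1, k + 1):
        s, r_t = mid[i - 1], r[i]
        left_dur.append(r_t - s)
        left_vals.append([interp(r_t + q * (r_t - s)) for q in grid_left])
    right_vals, right_dur = [], []
    for i in range(k):
        r_t, e = r[i], mid[i]
        right_dur.append(e - r_t)
        right_vals.append([interp(r_t + q * (e - r_t)) for q in grid_right])

    def median(values):
        v = sorted(values)
        mid_i = len(v) // 2
        return v[mid_i] if len(v) % 2 else (v[mid_i - 1] + v[mid_i]) / 2.0

    template_left = [median([row[p] for row in left_vals]) for p in range(n_half + 1)]
    template_right = [median([row[p] for row in right_vals]) for p in range(n_half + 1)]
    center = median([row[-1] for row in left_vals] + [row[0] for row in right_vals])
    template_left[-1] = center
    template_right[0] = center
    full = template_left + template_right[1:]
    amplitude = max(full) - min(full)

    phi = [math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)
           for x in [(i - k / 2) * (2.0 * weight_span / k) for i in range(k + 1)]]
    notch_half = qrs_notch_ms / 2000.0

    num = den = 0.0
    for i in range(k):  # left segment i+1 anchored at R_{i+1}
        for p, q in enumerate(grid_left):
            w = 0.0 if abs(q) * left_dur[i] <= notch_half else phi[i + 1]
            d = left_vals[i][p] - template_left[p]
            num += w * d * d
            den += w
    for i in range(k):  # right segment i anchored at R_i
        for p, q in enumerate(grid_right):
            w = 0.0 if abs(q) * right_dur[i] <= notch_half else phi[i]
            d = right_vals[i][p] - template_right[p]
            num += w * d * d
            den += w
    return num / (amplitude * den)
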