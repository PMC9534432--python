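"""Local alignment of RR-interval sequences (Smith-Waterman for numbers).

Two inter-beat interval sequences — a ground-truth reference and a query
from another device or detector — are aligned locally with a
Smith-Waterman-style dynamic program whose match reward is a capped
quadratic in the interval difference:

    s(a, b) = max(0, 1 - (a - b)**2 / 1000)        [a, b in ms]

so equal intervals score 1, a 10 ms deviation 0.9, a 20 ms deviation 0.6
and anything beyond ~31.6 ms scores 0.  A gap in the query (a deletion,
i.e. a missed beat) costs 1.0; a gap in the reference (an insertion, i.e. a
spurious beat splitting one interval) *adds* 0.9, because an insertion is
always accompanied by a mismatch already scored 0 and penalizing it again
would push the optimum away from the true pairing.  The positive insertion
reward means a pathological query can inflate the score with gap padding;
that is a property of the scheme, documented rather than patched.

From the traceback, alignment columns are classified (match/mismatch within
a 50 ms tolerance, insertion, deletion) and condensed into error counts:
false positives (insertions), false negatives (deletions) and misplaced
beats — a shifted beat produces two adjacent wrong intervals whose sums
agree, which counts as one misplaced event.

This works on *unsynchronized* data: no common clock, resampling or offset
estimation is needed, which is the point of aligning intervals instead of
time stamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RRSequence

__all__ = [
    "AlignParams",
    "AlignmentColumn",
    "RRAlignment",
    "ErrorCounts",
    "reward",
    "build_score_matrix",
    "traceback",
    "classify_errors",
    "align_rr",
]

# full O(mn) matrices only; refuse sizes that would need tens of GiB
_MAX_CELLS = 200_000_000


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme and classification tolerance.

    reward_scale : denominator of the quadratic reward, ms² (default 1000).
    deletion_penalty : score subtracted for a gap in the query (default 1.0).
    insertion_reward : score *added* for a gap in the reference (default 0.9).
    tolerance_ms : |a - b| bound separating match from mismatch columns
        (default 50 ms).  Independent of the reward: a 30 ms deviation has
        reward 0.1 yet is still a match-kind column; the reward shapes only
        the optimization.
    """

    reward_scale: float = 1000.0
    deletion_penalty: float = 1.0
    insertion_reward: float = 0.9
    tolerance_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.reward_scale <= 0:
            raise ValueError("reward_scale must be > 0")
        if self.tolerance_ms < 0:
            raise ValueError("tolerance_ms must be >= 0")


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column: paired indices or a gap, plus its kind."""

    ref_index: int | None
    query_index: int | None
    kind: str  # match | mismatch | insertion | deletion


@dataclass(frozen=True)
class RRAlignment:
    """A scored local alignment of two RR sequences."""

    columns: tuple[AlignmentColumn, ...]
    score: float
    ref_start: int | None = None  # 0-based index of first aligned ref interval
    ref_end: int | None = None  # index one past the last aligned ref interval
    query_start: int | None = None
    query_end: int | None = None


@dataclass(frozen=True)
class ErrorCounts:
    """Beat-level error counts derived from an alignment."""

    fp: int  # spurious beats (insertion columns)
    fn: int  # missed beats (deletion columns)
    misplaced: int  # shifted-beat events


def reward(a: float, b: float, scale: float = 1000.0) -> float:
    """Capped quadratic reward for pairing intervals ``a`` and ``b`` (ms)."""
    return max(0.0, 1.0 - (a - b) ** 2 / scale)


def build_score_matrix(
    ref: RRSequence, query: RRSequence, params: AlignParams | None = None
) -> np.ndarray:
    """Fill the (m+1)×(n+1) local-alignment score matrix H.

    First row and column are 0; every other cell is the maximum of 0 (start
    afresh), the diagonal predecessor plus the pair reward, the vertical
    predecessor minus the deletion penalty, and the horizontal predecessor
    plus the insertion reward.  All entries are >= 0.
    """
    params = params or AlignParams()
    a = np.asarray(ref.intervals, dtype=float)
    b = np.asarray(query.intervals, dtype=float)
    m, n = a.size, b.size
    if (m + 1) * (n + 1) > _MAX_CELLS:
        raise MemoryError(f"score matrix {m + 1}x{n + 1} exceeds the size guard")
    H = np.zeros((m + 1, n + 1))
    scale = params.reward_scale
    dele = params.deletion_penalty
    ins = params.insertion_reward
    for i in range(1, m + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            diff = ai - b[j - 1]
            s = 1.0 - diff * diff / scale
            if s < 0.0:
                s = 0.0
            best = prev[j - 1] + s
            cand = prev[j] - dele
            if cand > best:
                best = cand
            cand = row[j - 1] + ins
            if cand > best:
                best = cand
            row[j] = best if best > 0.0 else 0.0
    return H


def traceback(
    H: np.ndarray, ref: RRSequence, query: RRSequence, params: AlignParams | None = None
) -> RRAlignment:
    """Extract the optimal local alignment from a filled score matrix.

    The path starts at the global maximum of H (ties broken toward the
    smallest reference index, then the smallest query index) and follows
    predecessors until a zero cell.  When several predecessors reproduce the
    cell score, the diagonal is preferred, then the deletion, then the
    insertion: pairings beat gaps, which also prevents the positive
    insertion reward from padding the path with degenerate gaps.
    """
    params = params or AlignParams()
    a = ref.intervals
    b = query.intervals
    flat = int(np.argmax(H))  # C order: ties favour smaller i, then smaller j
    i, j = divmod(flat, H.shape[1])
    score = float(H[i, j])
    if score <= 0.0:
        return RRAlignment(columns=(), score=0.0)
    end_i, end_j = i, j
    columns: list[AlignmentColumn] = []
    eps = 1e-9
    while H[i, j] > eps:
        h = H[i, j]
        if (
            i >= 1
            and j >= 1
            and abs(H[i - 1, j - 1] + reward(a[i - 1], b[j - 1], params.reward_scale) - h) <= eps
        ):
            kind = "match" if abs(a[i - 1] - b[j - 1]) <= params.tolerance_ms else "mismatch"
            columns.append(AlignmentColumn(ref_index=i - 1, query_index=j - 1, kind=kind))
            i, j = i - 1, j - 1
        elif i >= 1 and abs(H[i - 1, j] - params.deletion_penalty - h) <= eps:
            columns.append(AlignmentColumn(ref_index=i - 1, query_index=None, kind="deletion"))
            i = i - 1
        elif j >= 1 and abs(H[i, j - 1] + params.insertion_reward - h) <= eps:
            columns.append(AlignmentColumn(ref_index=None, query_index=j - 1, kind="insertion"))
            j = j - 1
        else:  # pragma: no cover - H not built from these inputs
            raise ValueError("score matrix is inconsistent with the sequences and parameters")
    columns.reverse()
    return RRAlignment(
        columns=tuple(columns),
        score=score,
        ref_start=i,
        ref_end=end_i,
        query_start=j,
        query_end=end_j,
    )


def classify_errors(
    alignment: RRAlignment,
    ref: RRSequence,
    query: RRSequence,
    params: AlignParams | None = None,
) -> ErrorCounts:
    """Condense alignment columns into fp / fn / misplaced counts.

    Insertion columns count as false positives, deletion columns as false
    negatives.  Misplaced-beat events are found by scanning each maximal
    run of non-match columns left to right while accumulating the
    reference-side and query-side interval sums; whenever the two sums
    agree within the tolerance, the group since the last closure is
    complete.  A compensated group containing a gap column is the
    signature of that insertion/deletion (one interval split into two, or
    two merged into one) and is already counted as fp/fn; a compensated
    group of pure mismatches is one misplaced beat (a shifted beat makes
    two adjacent wrong intervals whose sums agree).  Mismatch columns left
    uncompensated at the end of a run count one event each.
    """
    params = params or AlignParams()
    a = ref.intervals
    b = query.intervals
    fp = sum(1 for c in alignment.columns if c.kind == "insertion")
    fn = sum(1 for c in alignment.columns if c.kind == "deletion")

    misplaced = 0
    run: list[AlignmentColumn] = []

    def flush(run: list[AlignmentColumn]) -> int:
        events = 0
        sum_ref = sum_query = 0.0
        has_gap = False
        n_mismatch = 0
        for col in run:
            if col.ref_index is not None:
                sum_ref += a[col.ref_index]
            if col.query_index is not None:
                sum_query += b[col.query_index]
            if col.kind == "mismatch":
                n_mismatch += 1
            else:
                has_gap = True
            if abs(sum_ref - sum_query) <= params.tolerance_ms:
                if n_mismatch and not has_gap:
                    events += 1
                sum_ref = sum_query = 0.0
                has_gap = False
                n_mismatch = 0
        events += n_mismatch  # uncompensated mismatches: one event each
        return events

    for col in alignment.columns:
        if col.kind == "match":
            if run:
                misplaced += flush(run)
                run = []
        else:
            run.append(col)
    if run:
        misplaced += flush(run)
    return ErrorCounts(fp=fp, fn=fn, misplaced=misplaced)


def align_rr(
    ref: RRSequence, query: RRSequence, params: AlignParams | None = None
) -> tuple[RRAlignment, ErrorCounts]:
    """Score, trace back and classify in one call."""
    params = params or AlignParams()
    H = build_score_matrix(ref, query, params)
    alignment = traceback(H, ref, query, params)
    counts = classify_errors(alignment, ref, query, params)
    return alignment, counts
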