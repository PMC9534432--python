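import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioqc import (
    AlignParams,
    RRSequence,
    align_rr,
    beats_from_rr,
    build_score_matrix,
    classify_errors,
    perturb_annotation,
    reward,
    rr_from_beats,
    traceback,
)
from cardioqc.rr_alignment import AlignmentColumn, RRAlignment

from oracles import brute_force_local_best


class TestReward:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(800, 800, 1.0), (800, 810, 0.9), (800, 820, 0.6), (800, 900, 0.0)],
    )
    def test_capped_quadratic(self, a, b, expected):
        assert reward(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(300, 2000, size=(50, 2)):
            assert reward(a, b) == reward(b, a)
            assert 0.0 <= reward(a, b) <= 1.0
        assert reward(1234.5, 1234.5) == 1.0


class TestScoreMatrix:
    def test_single_pair(self):
        H = build_score_matrix(RRSequence([800.0]), RRSequence([800.0]))
        assert H[1, 1] == 1.0

    def test_empty_query_all_zero(self):
        H = build_score_matrix(RRSequence([800.0]), RRSequence(np.empty(0)))
        assert np.all(H == 0)

    def test_four_identical_intervals(self):
        seq = RRSequence([800.0, 810.0, 790.0, 805.0])
        H = build_score_matrix(seq, seq)
        assert H.max() == pytest.approx(4.0, abs=1e-12)
        assert brute_force_local_best(seq.intervals, seq.intervals) == pytest.approx(4.0)

    intervals = st.lists(st.floats(min_value=300.0, max_value=2000.0), max_size=10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=intervals, b=intervals)
    def test_base_cases_and_nonnegativity(self, a, b):
        H = build_score_matrix(RRSequence(np.array(a)), RRSequence(np.array(b)))
        assert np.all(H[0, :] == 0) and np.all(H[:, 0] == 0)
        assert np.all(H >= 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(x=st.lists(st.floats(min_value=300.0, max_value=2000.0), min_size=1, max_size=15))
    def test_self_alignment_scores_length(self, x):
        seq = RRSequence(np.array(x))
        al, counts = align_rr(seq, seq)
        assert al.score == pytest.approx(len(x))
        assert (counts.fp, counts.fn, counts.misplaced) == (0, 0, 0)

    def test_matches_exhaustive_enumeration(self):
        """DP maximum equals brute-force path enumeration for tiny inputs."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            m, n = rng.integers(0, 7, size=2)
            a = rng.uniform(600, 1000, m)
            b = rng.uniform(600, 1000, n)
            H = build_score_matrix(RRSequence(a), RRSequence(b))
            assert H.max() == pytest.approx(brute_force_local_best(a, b), abs=1e-9)


class TestTraceback:
    def test_identical_sequences(self):
        seq = RRSequence([800.0, 820.0, 790.0, 810.0, 805.0])
        H = build_score_matrix(seq, seq)
        al = traceback(H, seq, seq)
        assert al.score == pytest.approx(5.0)
        assert [c.kind for c in al.columns] == ["match"] * 5

    def test_local_alignment_trims_unmatched_tail(self):
        ref = RRSequence([800.0, 800.0, 800.0])
        query = RRSequence([800.0, 800.0])
        al = traceback(build_score_matrix(ref, query), ref, query)
        assert sum(1 for c in al.columns if c.kind == "match") == 2
        assert not any(c.kind == "deletion" for c in al.columns)

    def test_split_interval_yields_insertion(self):
        """A spurious beat splits one interval; flanks stay matched."""
        ref = RRSequence([800.0, 805.0, 790.0])
        query = RRSequence([800.0, 400.0, 405.0, 790.0])
        al = traceback(build_score_matrix(ref, query), ref, query)
        kinds = [c.kind for c in al.columns]
        assert kinds.count("insertion") >= 1
        assert al.columns[0].kind == "match" and al.columns[-1].kind == "match"
        assert al.score == pytest.approx(
            brute_force_local_best(ref.intervals, query.intervals), abs=1e-9
        )

    def test_all_zero_matrix_gives_empty_alignment(self):
        ref = RRSequence(np.empty(0))
        query = RRSequence([800.0, 2000.0])
        al = traceback(build_score_matrix(ref, query), ref, query)
        assert al.columns == () and al.score == 0.0

    def test_lone_mismatched_pair_becomes_rewarded_insertion(self):
        """With no context, a single wildly different query interval is
        absorbed as a +0.9 insertion rather than a 0-reward mismatch — a
        documented consequence of the positive insertion reward."""
        ref = RRSequence([800.0])
        query = RRSequence([2000.0])
        al = traceback(build_score_matrix(ref, query), ref, query)
        assert [c.kind for c in al.columns] == ["insertion"]
        assert al.score == pytest.approx(0.9)

    def test_score_consistency_along_path(self):
        """Summed column contributions reproduce the start-cell score."""
        rng = np.random.default_rng(5)
        params = AlignParams()
        for _ in range(10):
            a = RRSequence(rng.uniform(500, 1100, 30))
            b = RRSequence(rng.uniform(500, 1100, 33))
            al = traceback(build_score_matrix(a, b, params), a, b, params)
            total = 0.0
            for c in al.columns:
                if c.kind in ("match", "mismatch"):
                    total += reward(a.intervals[c.ref_index], b.intervals[c.query_index])
                elif c.kind == "deletion":
                    total -= params.deletion_penalty
                else:
                    total += params.insertion_reward
            assert total == pytest.approx(al.score, abs=1e-9)


def make_alignment(columns):
    return RRAlignment(columns=tuple(columns), score=0.0)


class TestClassifyErrors:
    def test_all_match_is_error_free(self):
        seq = RRSequence([800.0] * 4)
        al, counts = align_rr(seq, seq)
        assert (counts.fp, counts.fn, counts.misplaced) == (0, 0, 0)

    def test_shifted_beat_counts_one_misplaced(self):
        """Two adjacent 60 ms-off mismatches with equal sums are one event."""
        ref = RRSequence([800.0, 800.0])
        query = RRSequence([740.0, 860.0])
        columns = [
            AlignmentColumn(ref_index=0, query_index=0, kind="mismatch"),
            AlignmentColumn(ref_index=1, query_index=1, kind="mismatch"),
        ]
        counts = classify_errors(make_alignment(columns), ref, query)
        assert (counts.fp, counts.fn, counts.misplaced) == (0, 0, 1)

    def test_shifted_beat_recovered_end_to_end(self):
        """A shift embedded in enough matched context survives the aligner."""
        base = 600.0 + 12.0 * np.arange(60)
        ref = RRSequence(base)
        query_vals = base.copy()
        query_vals[30] += 80.0
        query_vals[31] -= 80.0
        _, counts = align_rr(ref, RRSequence(query_vals))
        assert (counts.fp, counts.fn, counts.misplaced) == (0, 0, 1)

    def test_split_interval_is_fp_not_misplaced(self):
        """The mismatch+insertion signature of a split interval compensates
        (ref sum == query sum) and is attributed to the insertion alone."""
        ref = RRSequence([800.0, 805.0, 790.0])
        query = RRSequence([800.0, 400.0, 405.0, 790.0])
        columns = [
            AlignmentColumn(ref_index=0, query_index=0, kind="match"),
            AlignmentColumn(ref_index=1, query_index=1, kind="mismatch"),
            AlignmentColumn(ref_index=None, query_index=2, kind="insertion"),
            AlignmentColumn(ref_index=2, query_index=3, kind="match"),
        ]
        counts = classify_errors(make_alignment(columns), ref, query)
        assert (counts.fp, counts.fn, counts.misplaced) == (1, 0, 0)

    def test_merged_interval_is_fn_not_misplaced(self):
        ref = RRSequence([800.0, 400.0, 405.0, 790.0])
        query = RRSequence([800.0, 805.0, 790.0])
        columns = [
            AlignmentColumn(ref_index=0, query_index=0, kind="match"),
            AlignmentColumn(ref_index=1, query_index=1, kind="mismatch"),
            AlignmentColumn(ref_index=2, query_index=None, kind="deletion"),
            AlignmentColumn(ref_index=3, query_index=2, kind="match"),
        ]
        counts = classify_errors(make_alignment(columns), ref, query)
        assert (counts.fp, counts.fn, counts.misplaced) == (0, 1, 0)

    def test_uncompensated_mismatches_count_one_each(self):
        ref = RRSequence([800.0, 800.0, 800.0])
        query = RRSequence([900.0, 920.0, 910.0])
        columns = [
            AlignmentColumn(ref_index=i, query_index=i, kind="mismatch") for i in range(3)
        ]
        counts = classify_errors(make_alignment(columns), ref, query)
        assert counts.misplaced == 3

    def test_both_empty(self):
        empty = RRSequence(np.empty(0))
        al, counts = align_rr(empty, empty)
        assert al.columns == () and (counts.fp, counts.fn, counts.misplaced) == (0, 0, 0)


class TestAlignRR:
    def test_self_alignment_of_random_sequences(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            x = RRSequence(rng.uniform(300, 2000, rng.integers(1, 40)))
            al, counts = align_rr(x, x)
            assert al.score == pytest.approx(len(x))
            assert (counts.fp, counts.fn, counts.misplaced) == (0, 0, 0)

    def test_unrelated_padding_leaves_core_pairing_intact(self):
        """Leading/trailing unrelated query intervals do not disturb the core.

        The aligner still pairs the embedded true segment value-for-value;
        the pads are absorbed as rewarded insertions (and monetizing the
        leading pads may trim the first core pair) — documented behaviour
        of the positive insertion reward.
        """
        ref = RRSequence(600.0 + 12.0 * np.arange(40))
        pad = list(2600.0 + 100.0 * np.arange(5))
        query = RRSequence(pad + list(ref.intervals) + pad[::-1])
        padded, counts = align_rr(ref, query)
        matches = [c for c in padded.columns if c.kind == "match"]
        assert len(matches) >= len(ref) - 1
        for c in matches:
            assert ref.intervals[c.ref_index] == query.intervals[c.query_index]
        assert counts.fn == 0 and counts.misplaced == 0

    def test_exact_recovery_on_identifiable_ramp(self, ramp_rr):
        """Planted insert/delete/shift errors are recovered exactly.

        On a monotone HR-ramp every off-diagonal pairing rewards below the
        insertion reward and neighbouring intervals can never compensate an
        80 ms shift, so the planted alignment is the unique optimum.
        """
        beats = beats_from_rr(ramp_rr, source="reference")
        for seed in range(1, 21):
            pert, log = perturb_annotation(
                beats, 1, 1, 1, shift_ms=80.0, min_separation=15, seed=seed, edge_margin=40
            )
            _, counts = align_rr(rr_from_beats(beats), rr_from_beats(pert))
            assert (counts.fp, counts.fn, counts.misplaced) == (1, 1, 1), f"seed {seed}"
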