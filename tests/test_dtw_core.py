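import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitdtw.dtw_core import (
    WarpAlignment,
    dtw_align,
    dtw_distance,
    find_stretch_regions,
    refine_and_score,
)
from oracles_dtw import min_cost_by_path_enumeration, min_cost_by_recursion

seq = st.lists(st.integers(0, 2), min_size=1, max_size=8)


class TestDtwAlign:
    def test_perfect_match_is_diagonal(self):
        s = [0.0, 1.5, -2.0, 3.0]
        a = dtw_align(s, s)
        assert a.distance == 0.0
        assert np.array_equal(a.path, np.column_stack([range(4), range(4)]))

    def test_repeated_template_sample_absorbed(self):
        # oracle: brute-force enumeration on the 3x4 grid gives cost 0
        assert min_cost_by_path_enumeration([0, 1, 2], [0, 1, 1, 2]) == 0
        assert dtw_align([0, 1, 2], [0, 1, 1, 2]).distance == 0.0

    def test_constant_mismatch_matches_enumeration(self):
        expected = min_cost_by_path_enumeration([0, 0], [1, 1])
        assert dtw_align([0, 0], [1, 1]).distance == expected

    def test_full_enumeration_small_grids(self):
        # every sequence pair of length <= 3 over {0,1,2}
        seqs = [
            list(s)
            for k in (1, 2, 3)
            for s in itertools.product((0, 1, 2), repeat=k)
        ]
        for q in seqs:
            for t in seqs:
                assert dtw_align(q, t).distance == min_cost_by_path_enumeration(q, t)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seq, seq)
    def test_matches_recursive_oracle(self, q, t):
        assert dtw_align(q, t).distance == min_cost_by_recursion(q, t)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq, seq)
    def test_distance_symmetric_nonnegative(self, q, t):
        d = dtw_align(q, t).distance
        assert d == dtw_align(t, q).distance
        assert d >= 0
        assert (d == 0) == bool(
            np.all([abs(q[i] - t[j]) == 0 for i, j in dtw_align(q, t).path])
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seq, seq)
    def test_path_is_valid_warping_path(self, q, t):
        path = dtw_align(q, t).path
        assert tuple(path[0]) == (0, 0)
        assert tuple(path[-1]) == (len(q) - 1, len(t) - 1)
        steps = np.diff(path, axis=0)
        assert np.all(steps >= 0)
        assert np.all(steps <= 1)
        assert np.all(steps.sum(axis=1) >= 1)

    def test_distance_equals_sum_of_local_costs_on_path(self):
        rng = np.random.default_rng(0)
        q, t = rng.normal(size=30), rng.normal(size=25)
        a = dtw_align(q, t)
        assert a.distance == pytest.approx(
            sum(abs(q[i] - t[j]) for i, j in a.path)
        )

    def test_distance_only_agrees_with_align(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q, t = rng.normal(size=17), rng.normal(size=23)
            assert dtw_distance(q, t) == pytest.approx(dtw_align(q, t).distance)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_align([], [1.0])


def _alignment_from_pairs(pairs):
    return WarpAlignment(path=np.asarray(pairs, dtype=int), distance=0.0)


class TestStretchRegions:
    def test_diagonal_has_no_regions(self):
        a = _alignment_from_pairs([(i, i) for i in range(20)])
        assert find_stretch_regions(a, template_length=20) == []

    def test_long_run_detected_with_borders(self):
        # template frame 5 absorbs query frames 5..16 (12 frames)
        pairs = [(i, i) for i in range(5)]
        pairs += [(5 + k, 5) for k in range(12)]
        pairs += [(17 + k, 6 + k) for k in range(3)]
        a = _alignment_from_pairs(pairs)
        regions = find_stretch_regions(a, template_length=100, min_fraction=0.10)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_query, r.end_query, r.length_frames) == (5, 17, 12)

    def test_run_below_threshold_ignored(self):
        pairs = [(i, i) for i in range(5)]
        pairs += [(5 + k, 5) for k in range(12)]
        pairs += [(17 + k, 6 + k) for k in range(3)]
        a = _alignment_from_pairs(pairs)
        assert find_stretch_regions(a, template_length=100, min_fraction=0.15) == []

    def test_bad_fraction_rejected(self):
        a = _alignment_from_pairs([(0, 0)])
        with pytest.raises(ValueError):
            find_stretch_regions(a, 10, min_fraction=1.5)


def _sine_template(n=100):
    return np.sin(2 * np.pi * 2 * np.arange(n) / n) * 3.0


class TestRefineAndScore:
    def test_window_equal_to_template(self):
        t = _sine_template()
        assert refine_and_score(t, t) == (0, 100, 0.0)

    def test_padding_is_trimmed(self):
        t = _sine_template()
        window = np.concatenate([t, np.zeros(30)])
        untrimmed = dtw_align(window, t).distance
        s, e, d = refine_and_score(window, t)
        assert d < untrimmed
        # recovered borders within 10% of the template length
        assert abs(s - 0) <= 10
        assert abs(e - 100) <= 10
        # exhaustive sub-window search confirms a strictly better section
        # than the untrimmed window exists, and ours is close to the optimum
        best = min(
            dtw_distance(window[a:b], t)
            for a in range(0, 31, 5)
            for b in range(a + 40, 131, 5)
        )
        assert best < untrimmed
        assert d <= best + 0.05 * untrimmed

    def test_short_window_guard_returns_untrimmed(self):
        t = _sine_template(100)
        window = t[:30]  # < 40% of the template; no trimming allowed
        s, e, d = refine_and_score(window, t)
        assert (s, e) == (0, 30)
        assert d == pytest.approx(dtw_align(window, t).distance)

    def test_never_worse_than_untrimmed(self):
        rng = np.random.default_rng(5)
        t = _sine_template(60)
        for _ in range(10):
            window = rng.normal(size=90) * 2
            _, _, d = refine_and_score(window, t)
            assert d <= dtw_align(window, t).distance + 1e-12
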