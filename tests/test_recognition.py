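import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitdtw as g
from gaitdtw.constants import NO_ACTIVITY
from gaitdtw.recognition import (
    AxisConfig,
    RecognitionConfig,
    classify,
    combine_axes,
    frame_probability,
    length_penalty,
    sliding_match,
)

WALK_CFG = AxisConfig(("AccX", "AccZ", "GyroX", "GyroY", "GyroZ"), {"AccZ": 2.0})


class TestFrameProbability:
    def test_perfect_match_scores_100(self):
        assert frame_probability(0.0, 120.0) == pytest.approx(100.0)

    def test_zero_at_threshold_and_above(self):
        assert frame_probability(120.0, 120.0) == 0.0
        assert frame_probability(130.0, 120.0) == 0.0

    def test_halfway_value(self):
        assert frame_probability(60.0, 120.0) == pytest.approx(101 - 101**0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_strictly_decreasing_below_threshold(self, a, b):
        if abs(a - b) < 1e-6:  # below float resolution of the formula
            return
        lo, hi = sorted([a, b])
        assert frame_probability(hi * 120, 120) < frame_probability(lo * 120, 120)

    def test_vectorized_matches_scalar(self):
        eds = np.array([0.0, 30.0, 119.9, 120.0, 500.0])
        vec = frame_probability(eds, 120.0)
        assert np.allclose(vec, [frame_probability(float(e), 120.0) for e in eds])

    def test_negative_ed_rejected(self):
        with pytest.raises(ValueError):
            frame_probability(-1.0, 120.0)


class TestCombineAxes:
    def test_weighted_mean_with_double_vertical(self):
        p = {"AccX": 80, "AccZ": 90, "GyroX": 70, "GyroY": 70, "GyroZ": 70}
        assert combine_axes(p, WALK_CFG) == pytest.approx((80 + 180 + 70 * 3) / 6)

    def test_three_zero_axes_veto(self):
        p = {"AccX": 80, "AccZ": 90, "GyroX": 0, "GyroY": 0, "GyroZ": 0}
        assert combine_axes(p, WALK_CFG) == 0.0

    def test_two_zero_axes_do_not_veto(self):
        p = {"AccX": 80, "AccZ": 90, "GyroX": 0, "GyroY": 0, "GyroZ": 60}
        assert combine_axes(p, WALK_CFG) > 0.0

    def test_all_zero(self):
        assert combine_axes({a: 0 for a in WALK_CFG.used}, WALK_CFG) == 0.0

    def test_missing_axis_rejected(self):
        with pytest.raises(ValueError, match="GyroZ"):
            combine_axes({a: 50 for a in WALK_CFG.used[:-1]}, WALK_CFG)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1.0, 100.0), min_size=5, max_size=5))
    def test_between_min_and_max_when_no_veto(self, values):
        p = dict(zip(WALK_CFG.used, values))
        out = combine_axes(p, WALK_CFG)
        assert min(values) - 1e-9 <= out <= max(values) + 1e-9


class TestLengthPenalty:
    def test_boundary_is_unpenalized(self):
        assert length_penalty(80.0, 50, 100) == 80.0

    def test_quarter_length_halves(self):
        assert length_penalty(80.0, 25, 100) == pytest.approx(40.0)

    def test_full_length_unchanged(self):
        assert length_penalty(80.0, 100, 100) == 80.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(0, 100), st.integers(1, 200))
    def test_never_increases(self, p, sec):
        assert length_penalty(p, sec, 100) <= p + 1e-12


class TestClassify:
    def test_argmax(self):
        p = {
            "walking": np.array([90.0]),
            "ascending_stairs": np.array([10.0]),
            "descending_stairs": np.array([0.0]),
        }
        assert classify(p)[0] == "walking"

    def test_all_zero_is_no_selected_activity(self):
        p = {a: np.zeros(3) for a in g.ACTIVITIES}
        assert list(classify(p)) == [NO_ACTIVITY] * 3

    def test_exact_tie_uses_fixed_order(self):
        p = {
            "walking": np.array([50.0]),
            "ascending_stairs": np.array([50.0]),
            "descending_stairs": np.array([20.0]),
        }
        assert classify(p)[0] == "walking"


def _sine(n, cycles=2, amp=3.0):
    return amp * np.sin(2 * np.pi * cycles * np.arange(n) / n)


class TestSlidingMatch:
    def test_signal_equal_to_template(self):
        t = _sine(100)
        ed, seclen = sliding_match(t, t)
        assert np.allclose(ed, 0.0)
        assert np.all(seclen == 100)

    def test_two_concatenated_copies_all_zero(self):
        t = _sine(100)
        ed, seclen = sliding_match(np.concatenate([t, t]), t)
        assert np.allclose(ed, 0.0, atol=1e-9)

    def test_constant_signal_fully_assigned_positive(self):
        t = _sine(100)
        ed, _ = sliding_match(np.zeros(400), t)
        assert np.all(np.isfinite(ed))
        assert np.all(ed > 0)

    def test_signal_shorter_than_template_still_matched(self):
        t = _sine(100)
        ed, _ = sliding_match(t[:40], t)
        assert ed.size == 40
        assert np.all(np.isfinite(ed))

    def test_full_coverage_on_noise(self):
        rng = np.random.default_rng(9)
        ed, seclen = sliding_match(rng.normal(size=777), _sine(100))
        assert np.all(np.isfinite(ed))
        assert np.all(seclen > 0)


class TestRecognize:
    def _template_set(self, wave):
        axes = {a: wave.copy() for a in g.AXES}
        return g.TemplateSet({
            act: g.template.ActivityTemplate(len(wave), {a: v + k for a, v in axes.items()})
            for k, act in enumerate(g.ACTIVITIES)
        })

    def test_repeated_template_copies_recovered(self):
        wave = _sine(100) + 9.81
        tset = self._template_set(wave)
        samples = np.column_stack([np.tile(wave, 8) for _ in g.AXES])
        rec = g.ImuRecording(samples)
        thr = {act: {a: 50.0 for a in g.AXES} for act in g.ACTIVITIES}
        scores = g.recognize(rec, tset, RecognitionConfig(thresholds=thr))
        frac_walking = np.mean(scores.labels == "walking")
        assert frac_walking >= 0.95

    def test_all_above_threshold_yields_no_activity(self):
        wave = _sine(100) + 9.81
        tset = self._template_set(wave)
        rec = g.ImuRecording(np.zeros((500, 6)))
        thr = {act: {a: 1e-6 for a in g.AXES} for act in g.ACTIVITIES}
        scores = g.recognize(rec, tset, RecognitionConfig(thresholds=thr))
        assert np.all(scores.labels == NO_ACTIVITY)

    def test_every_frame_gets_exactly_one_label(self, recognized_b):
        scores, _ = recognized_b
        valid = set(g.ACTIVITIES) | {NO_ACTIVITY}
        assert scores.labels.size == scores.n_frames
        assert set(scores.labels) <= valid

    def test_probabilities_in_range(self, recognized_b):
        scores, _ = recognized_b
        for act, p in scores.p_overall.items():
            assert np.all(p >= 0) and np.all(p <= 100)

    def test_output_csv_schema(self, recognized_b, tmp_path):
        scores, _ = recognized_b
        p = tmp_path / "pred.csv"
        scores.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["frame", "label", "p_walking", "p_ascending", "p_descending"]
        assert len(df) == scores.n_frames

    def test_missing_template_rejected(self):
        tset = g.TemplateSet({})
        with pytest.raises(ValueError):
            g.recognize(g.ImuRecording(np.zeros((10, 6))), tset)


class TestConfigRoundtrip:
    def test_yaml_and_json(self, tmp_path):
        cfg = RecognitionConfig()
        for name in ("cfg.yaml", "cfg.json"):
            p = tmp_path / name
            cfg.to_file(p)
            back = RecognitionConfig.from_file(p)
            assert back.thresholds == cfg.thresholds
            assert back.window_factor == cfg.window_factor
            assert back.axes["walking"].weight("AccZ") == 2.0

    def test_defaults_match_reference_table(self):
        cfg = RecognitionConfig()
        assert cfg.thresholds["walking"]["AccX"] == 120
        assert cfg.thresholds["descending_stairs"]["GyroZ"] == 25
        assert set(cfg.axes["ascending_stairs"].used) == {"AccX", "AccY", "AccZ", "GyroY"}

    def test_missing_threshold_for_used_axis_rejected(self):
        with pytest.raises(ValueError):
            RecognitionConfig(thresholds={"walking": {"AccX": 120}})
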