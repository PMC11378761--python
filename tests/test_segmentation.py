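"""Trial detection, dropout repair and representative-curve averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expanding_procrustes.io import CHANNELS, Placement, SensorStream
from expanding_procrustes.segmentation import (
    AlignmentError,
    RepairError,
    TaskSpec,
    TrialSegment,
    apply_boundaries,
    average_trials,
    detect_trials,
    fill_dropouts,
    resample_trial,
    trial_duration,
)


def _stream(values: dict, rate: float = 10.0) -> SensorStream:
    n = len(next(iter(values.values())))
    data = {"t": np.arange(n) / rate}
    for ch in CHANNELS:
        data[ch] = values.get(ch, np.zeros(n))
    return SensorStream(Placement("right", "upper_arm"), pd.DataFrame(data))


def _pulse(n: int, center: int, width: float, amp: float = 1.0) -> np.ndarray:
    x = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestFillDropouts:
    def test_interior_midpoint_interpolation(self):
        s = _stream({"ay": np.array([1.0, np.nan, 3.0])})
        out = fill_dropouts(s)
        assert out.channel("ay").tolist() == [1.0, 2.0, 3.0]
        assert not out.missing_mask.any().any()

    def test_edge_runs_take_nearest_value(self):
        s = _stream({"ay": np.array([np.nan, 5.0, 7.0, np.nan, np.nan])})
        out = fill_dropouts(s)
        assert out.channel("ay").tolist() == [5.0, 5.0, 7.0, 7.0, 7.0]

    def test_no_missing_is_identity(self):
        s = _stream({"ay": np.array([1.0, 4.0, 2.0])})
        out = fill_dropouts(s)
        pd.testing.assert_frame_equal(out.data, s.data)

    def test_entirely_missing_channel_names_it(self):
        s = _stream({"gz": np.array([np.nan, np.nan, np.nan])})
        with pytest.raises(RepairError, match="gz"):
            fill_dropouts(s)


class TestDetectTrials:
    def _brute_force_extrema(self, y):
        """Independent enumeration of strict interior local maxima."""
        return [
            i
            for i in range(1, len(y) - 1)
            if y[i] > y[i - 1] and y[i] >= y[i + 1]
        ]

    def test_single_pulse_reach_spans_baseline_to_baseline(self):
        y = np.concatenate([np.zeros(20), _pulse(30, 15, 4.0), np.zeros(20)])
        segs = detect_trials(y, TaskSpec(task="reach"))
        assert len(segs) == 1
        (seg,) = segs
        peaks = self._brute_force_extrema(y)
        assert len(peaks) == 1
        assert seg.start < peaks[0] < seg.end
        # boundaries sit at the flat neutral baseline on either side
        assert y[seg.start] == pytest.approx(y.min(), abs=1e-12)
        assert y[seg.end] == pytest.approx(y.min(), abs=1e-12)

    def test_pulse_train_yields_one_trial_per_pulse(self):
        block = np.concatenate([np.zeros(10), _pulse(30, 15, 3.0)])
        y = np.concatenate([np.tile(block, 10), np.zeros(10)])
        segs = detect_trials(y, TaskSpec(task="reach"))
        assert len(segs) == 10
        assert [s.trial_no for s in segs] == list(range(1, 11))
        starts = [s.start for s in segs]
        ends = [s.end for s in segs]
        assert all(e <= s2 for e, s2 in zip(ends, starts[1:]))  # non-overlap

    def test_constant_series_yields_no_trials(self, caplog):
        segs = detect_trials(np.full(100, 3.7), TaskSpec(task="reach"))
        assert segs == []

    def test_offset_invariance(self):
        y = np.concatenate([np.zeros(20), _pulse(30, 15, 4.0), np.zeros(20)])
        a = detect_trials(y, TaskSpec(task="reach"))
        b = detect_trials(y + 123.4, TaskSpec(task="reach"))
        assert [(s.start, s.end) for s in a] == [(s.start, s.end) for s in b]

    def test_button_rule_stops_at_last_peak(self):
        # two pulses between neutral returns; buttoning ends at the last one
        trial = _pulse(60, 18, 4.0) + _pulse(60, 42, 4.0) + 0.5
        trial[0] = trial[-1] = 0.0
        y = np.concatenate([np.zeros(5), trial, np.zeros(5)])
        segs = detect_trials(y, TaskSpec(task="button"))
        assert len(segs) == 1
        peaks = [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] >= y[i + 1]]
        assert segs[0].end == peaks[-1] + 1


class TestApplyBoundaries:
    def _six_streams(self, n=50):
        return {
            Placement(side, seg): _stream({"ay": np.arange(n, dtype=float)})
            for side in ("left", "right")
            for seg in ("upper_arm", "forearm", "hand")
        }

    def test_two_segments_give_twelve_equal_length_curves(self):
        streams = self._six_streams()
        segs = [TrialSegment(0, 10, 1), TrialSegment(20, 35, 2)]
        out = apply_boundaries(streams, segs)
        assert len(out) == 6
        for curves in out.values():
            assert [c.shape for c in curves] == [(10, 3), (15, 3)]

    def test_segment_beyond_length_is_alignment_error(self):
        with pytest.raises(AlignmentError):
            apply_boundaries(self._six_streams(50), [TrialSegment(40, 60, 1)])

    def test_misaligned_streams_rejected(self):
        streams = self._six_streams(50)
        streams[Placement("left", "hand")] = _stream({"ay": np.zeros(49)})
        with pytest.raises(AlignmentError):
            apply_boundaries(streams, [TrialSegment(0, 10, 1)])

    def test_empty_segments_give_empty_result(self):
        out = apply_boundaries(self._six_streams(), [])
        assert all(v == [] for v in out.values())


class TestResampleAverage:
    def test_same_length_is_identity(self, rng):
        c = rng.normal(size=(20, 3))
        assert np.array_equal(resample_trial(c, 20), c)

    def test_linear_ramp_stays_linear_with_exact_endpoints(self):
        ramp = np.linspace([0, 0, 0], [9, 18, -9], 10)
        out = resample_trial(ramp, 25)
        assert out[0] == pytest.approx([0, 0, 0])
        assert out[-1] == pytest.approx([9, 18, -9])
        diffs = np.diff(out, axis=0)
        assert np.allclose(diffs, diffs[0])

    def test_two_points_resample_to_chord(self):
        out = resample_trial(np.array([[0.0, 0.0, 0.0], [4.0, 8.0, -4.0]]), 5)
        assert np.allclose(out[:, 0], [0, 1, 2, 3, 4])

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            resample_trial(np.zeros((5, 3)), 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=2, max_value=40))
    def test_resample_idempotent_at_fixed_n(self, k, n):
        rng = np.random.default_rng(k * 100 + n)
        c = rng.normal(size=(k, 3))
        once = resample_trial(c, n)
        assert np.allclose(resample_trial(once, n), once)

    def test_identical_trials_average_to_any_one(self, rng):
        c = rng.normal(size=(30, 3))
        avg = average_trials([c.copy() for _ in range(10)])
        assert avg.n_trials == 10
        assert np.allclose(avg.values, c)

    def test_opposite_trials_cancel(self, rng):
        c = rng.normal(size=(25, 3))
        avg = average_trials([c, -c])
        assert np.allclose(avg.values, 0.0)

    def test_mean_length_average_matches_pointwise_oracle(self):
        lengths = [30, 33, 27]
        rng = np.random.default_rng(0)
        trials = [rng.normal(size=(k, 3)) for k in lengths]
        avg = average_trials(trials)
        assert avg.N == 30  # round(mean(30, 33, 27))

        def interp_at(curve, frac, axis):
            # plain-loop linear interpolation, independent of resample_trial
            pos = frac * (curve.shape[0] - 1)
            i = int(np.floor(pos))
            if i >= curve.shape[0] - 1:
                return curve[-1, axis]
            w = pos - i
            return (1 - w) * curve[i, axis] + w * curve[i + 1, axis]

        for probe in (0, 15, 29):
            frac = probe / 29
            for axis in range(3):
                expected = np.mean([interp_at(t, frac, axis) for t in trials])
                assert avg.values[probe, axis] == pytest.approx(expected)

    def test_empty_trial_list_rejected(self):
        with pytest.raises(ValueError):
            average_trials([])


class TestTrialDuration:
    @pytest.mark.parametrize("length,rate,expected", [(33, 10.0, 3.3), (10, 10.0, 1.0)])
    def test_duration_arithmetic(self, length, rate, expected):
        assert trial_duration(TrialSegment(0, length, 1), rate) == pytest.approx(expected)

    def test_mean_duration_equals_covered_span(self):
        rng = np.random.default_rng(3)
        starts = np.cumsum(rng.integers(5, 15, size=10))
        lengths = rng.integers(20, 40, size=10)
        segs = [
            TrialSegment(int(s), int(s + l), i + 1)
            for i, (s, l) in enumerate(zip(starts, lengths))
        ]
        mean_dur = np.mean([trial_duration(s) for s in segs])
        assert mean_dur == pytest.approx(lengths.sum() / 10 / 10.0)
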