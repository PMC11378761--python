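"""Windowed scan, seed selection, interval expansion and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expanding_procrustes.expanding import (
    CongruenceInterval,
    coordinate_pair,
    coordination_score,
    expand,
    log_normalize,
    percent_similarity,
    scan,
    select_seed,
    temporal_gate,
    window_length,
)
from expanding_procrustes.procrustes import dissimilarity
from expanding_procrustes.synthetic import (
    MotionParams,
    make_task_curve,
    plant_congruent_pair,
)


def _planted(seed, lo=70, hi=129, noise_frac=0.0, n=200):
    base = make_task_curve(MotionParams(task="reach", trial_len=n, seed=seed, noise_sd=0.01))
    span_rms = float(np.sqrt((base[lo : hi + 1] ** 2).mean()))
    return plant_congruent_pair(base, (lo, hi), noise_sd=noise_frac * span_rms, seed=seed + 1000)


class TestScan:
    def test_identical_curves_all_zero(self, reach_curve):
        prof = scan(reach_curve, reach_curve)
        assert prof.di.shape == (200 - prof.w + 1,)
        assert np.allclose(prof.di, 0.0, atol=1e-12)

    def test_profile_matches_independent_loop(self, reach_curve, rng):
        other = rng.normal(size=reach_curve.shape)
        prof = scan(reach_curve, other)
        w = prof.w
        expected = [
            dissimilarity(reach_curve[s : s + w], other[s : s + w])
            for s in range(reach_curve.shape[0] - w + 1)
        ]
        assert np.allclose(prof.di, expected)

    def test_planted_span_attracts_argmin(self):
        pair = _planted(seed=5, noise_frac=0.02)
        prof = scan(pair.right.values, pair.left.values)
        lo, hi = pair.truth
        assert lo <= int(np.argmin(prof.di)) <= hi - prof.w + 1

    def test_window_clamps_to_two_on_short_curves(self, rng):
        curve = rng.normal(size=(5, 3))
        prof = scan(curve, curve, w_frac=0.10)
        assert prof.w == 2
        assert prof.di.size == 4

    def test_shorter_than_window_rejected(self, rng):
        c = rng.normal(size=(1, 3))
        with pytest.raises(ValueError):
            scan(c, c)


class TestSelectSeed:
    def test_earliest_tie_wins(self):
        from expanding_procrustes.expanding import ScanProfile

        assert select_seed(ScanProfile(w=2, di=np.array([0.3, 0.1, 0.1]))) == 1
        assert select_seed(ScanProfile(w=2, di=np.full(7, 0.2))) == 0

    def test_matches_brute_force_argmin(self, rng):
        from expanding_procrustes.expanding import ScanProfile

        di = rng.uniform(size=50)
        best = min(range(50), key=lambda i: di[i])
        assert select_seed(ScanProfile(w=5, di=di)) == best

    def test_empty_profile_rejected(self):
        from expanding_procrustes.expanding import ScanProfile

        with pytest.raises(ValueError):
            select_seed(ScanProfile(w=2, di=np.array([])))


class TestExpand:
    def test_identical_curves_cover_everything(self, reach_curve):
        prof = scan(reach_curve, reach_curve)
        iv = expand(reach_curve, reach_curve, select_seed(prof))
        assert (iv.min_idx, iv.max_idx) == (0, reach_curve.shape[0] - 1)
        assert iv.di == pytest.approx(0.0, abs=1e-12)

    def test_seed_above_threshold_is_empty(self, reach_curve, rng):
        noise = rng.normal(size=reach_curve.shape)
        prof = scan(reach_curve, noise)
        seed = select_seed(prof)
        if prof.di[seed] > 0.15:  # typical for independent noise
            iv = expand(reach_curve, noise, seed)
            assert iv.empty
            assert percent_similarity(iv, reach_curve.shape[0]) == 0.0

    def test_explicit_zero_similarity_rule(self, reach_curve):
        # reversed-time copy: spatially rich but not congruent anywhere
        flipped = reach_curve[::-1] * np.array([1.0, -1.0, 1.0]) + np.array([0.3, 0.0, -0.2])
        prof = scan(reach_curve, flipped)
        seed = select_seed(prof)
        iv = expand(reach_curve, flipped, seed, tau=min(0.15, float(prof.di[seed]) / 2))
        assert iv.empty

    @pytest.mark.parametrize("seed", [1, 2, 6, 8])
    def test_contract_on_planted_pairs(self, seed):
        pair = _planted(seed=seed, noise_frac=0.03)
        X, Y = pair.right.values, pair.left.values
        prof = scan(X, Y)
        s = select_seed(prof)
        iv = expand(X, Y, s)
        assert not iv.empty
        # containment of the seed window
        assert iv.min_idx <= s and s + prof.w - 1 <= iv.max_idx
        # threshold compliance
        assert iv.di <= 0.15
        # local maximality: one-sample extension at either free edge fails
        n = X.shape[0]
        if iv.max_idx + 1 < n:
            assert dissimilarity(X[iv.min_idx : iv.max_idx + 2], Y[iv.min_idx : iv.max_idx + 2]) > 0.15
        if iv.min_idx - 1 >= 0:
            assert dissimilarity(X[iv.min_idx - 1 : iv.max_idx + 1], Y[iv.min_idx - 1 : iv.max_idx + 1]) > 0.15

    @pytest.mark.parametrize("seed", [3, 9])
    def test_interval_monotone_in_threshold(self, seed):
        pair = _planted(seed=seed, noise_frac=0.03)
        X, Y = pair.right.values, pair.left.values
        s = select_seed(scan(X, Y))
        prev_len = -1
        for tau in (0.05, 0.10, 0.15, 0.30, 0.60):
            iv = expand(X, Y, s, tau=tau)
            assert iv.length >= prev_len
            prev_len = iv.length

    def test_recovery_of_planted_interval(self):
        jacc = []
        for seed in range(50):
            pair = _planted(seed=seed, noise_frac=0.05)
            lo, hi = pair.truth
            res = coordinate_pair(pair.right.values, pair.left.values)
            if res.interval.empty:
                jacc.append(0.0)
                continue
            a, b = res.interval.min_idx, res.interval.max_idx
            inter = max(0, min(b, hi) - max(a, lo) + 1)
            union = (b - a + 1) + (hi - lo + 1) - inter
            jacc.append(inter / union)
        assert float(np.median(jacc)) >= 0.6


class TestScoring:
    def test_percent_of_full_and_partial_intervals(self):
        full = CongruenceInterval(0, 99, 0.05, 0, empty=False)
        part = CongruenceInterval(10, 34, 0.05, 12, empty=False)
        assert percent_similarity(full, 100) == 100.0
        assert percent_similarity(part, 100) == 25.0
        assert percent_similarity(CongruenceInterval(), 100) == 0.0

    @pytest.mark.parametrize(
        "percent,di,expected",
        [(50.0, 0.1, 500.0), (0.0, 0.5, 0.0), (100.0, 0.0, 1e8)],
    )
    def test_score_arithmetic_including_epsilon_floor(self, percent, di, expected):
        assert coordination_score(percent, di) == pytest.approx(expected)

    def test_log_normalize_examples_and_order(self, rng):
        assert log_normalize([0.0])[0] == 0.0
        assert log_normalize([np.e - 1])[0] == pytest.approx(1.0)
        a = rng.uniform(0, 1000, size=100)
        b = a + rng.uniform(0.1, 10, size=100)
        assert np.all(log_normalize(b) > log_normalize(a))
        with pytest.raises(ValueError):
            log_normalize([-1.0])

    def test_self_coordination_is_total(self, reach_curve):
        res = coordinate_pair(reach_curve, reach_curve)
        assert res.percent_similarity == 100.0
        assert res.di == pytest.approx(0.0, abs=1e-12)


class TestTemporalGate:
    def test_overlapping_stage_keeps_interval(self):
        iv = CongruenceInterval(10, 30, 0.1, 12, empty=False)
        assert temporal_gate(iv, [(25, 60)]) is iv

    def test_disjoint_stages_zero_the_interval(self):
        iv = CongruenceInterval(10, 30, 0.1, 12, empty=False)
        out = temporal_gate(iv, [(50, 90), (95, 99)])
        assert out.empty

    def test_empty_interval_passes_through(self):
        iv = CongruenceInterval()
        assert temporal_gate(iv, [(0, 10)]).empty

    def test_single_sample_overlap_suffices(self):
        iv = CongruenceInterval(10, 30, 0.1, 12, empty=False)
        assert not temporal_gate(iv, [(30, 40)]).empty
        assert temporal_gate(iv, [(31, 40)]).empty
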