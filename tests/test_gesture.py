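"""Moving-SD gesture detection: magnitude, windows, merge rule, power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from gestwear import states
from gestwear.errors import DegenerateEventError
from gestwear.gesture import (
    GestureConfig,
    daily_gesture_counts,
    detect_gesture_events,
    gesture_power,
    magnitude,
    moving_sd,
)
from gestwear.io import DaySegment

from conftest import make_recording

FS = 20.0


def brute_force_moving_sd(mag, time_s, fs, cfg):
    """Direct per-window recomputation (the independent oracle)."""
    from gestwear.io import covered_runs

    w = int(round(cfg.window_s * fs))
    out = []
    for i0, i1 in covered_runs(time_s, fs, cfg.max_gap_factor):
        for i in range(i0, i1 - w + 1):
            out.append(np.std(mag[i : i + w]))
    return np.array(out)


def _stationary_signal(n, idle_sd, bursts, seed=0):
    """Idle z-gravity signal with (start_idx, stop_idx, sd) noise bursts."""
    rng = np.random.default_rng(seed)
    acc = rng.normal(0, idle_sd, (n, 3)) + [0, 0, 1.0]
    for i0, i1, sd in bursts:
        acc[i0:i1] += rng.normal(0, sd, (i1 - i0, 3))
    t = np.arange(n) / FS
    return t, acc


class TestMagnitude:
    def test_three_four_five(self):
        assert magnitude(np.array([[0.6, 0.8, 0.0]]))[0] == pytest.approx(1.0)

    def test_pure_gravity_constant(self):
        assert np.all(magnitude(np.tile([0.0, 0.0, 1.0], (50, 1))) == 1.0)

    def test_rotation_invariance(self, rng):
        acc = rng.normal(0, 0.5, (200, 3))
        m = magnitude(acc)
        for seed in range(5):
            Q = ortho_group.rvs(3, random_state=seed)
            np.testing.assert_allclose(magnitude(acc @ Q.T), m, atol=1e-12)


class TestMovingSD:
    def test_constant_series_zero(self):
        t = np.arange(100) / FS
        msd = moving_sd(np.ones(100), t, FS, GestureConfig())
        assert np.all(msd.sd == 0.0)

    def test_alternating_closed_form(self):
        a = 0.3
        m = 1.0 + a * (-1.0) ** np.arange(100)
        msd = moving_sd(m, np.arange(100) / FS, FS, GestureConfig())
        np.testing.assert_allclose(msd.sd, a, atol=1e-12)

    def test_matches_bruteforce_with_gaps(self, rng):
        cfg = GestureConfig()
        for _ in range(50):
            n = rng.integers(25, 200)
            dts = rng.choice([1 / FS, 5.0], size=n - 1, p=[0.97, 0.03])
            t = np.cumsum(np.concatenate([[0.0], dts]))
            m = 1.0 + rng.normal(0, 0.05, n)
            msd = moving_sd(m, t, FS, cfg)
            oracle = brute_force_moving_sd(m, t, FS, cfg)
            np.testing.assert_allclose(msd.sd, oracle, atol=1e-9)

    def test_windows_never_straddle_gaps(self):
        t = np.concatenate([np.arange(30) / FS, 100 + np.arange(30) / FS])
        msd = moving_sd(np.ones(60), t, FS, GestureConfig())
        # 11 window positions per 30-sample run
        assert msd.sd.size == 22
        assert set(np.bincount(msd.run_id)) == {11}


class TestDetection:
    def test_single_burst_single_event_within_one_second(self):
        n = int(60 * FS)
        b0, b1 = int(20 * FS), int(23 * FS)
        t, acc = _stationary_signal(n, 0.005, [(b0, b1, 0.05)], seed=1)
        code = np.zeros(n, np.int8)
        events = detect_gesture_events(magnitude(acc), t, code, FS, GestureConfig())
        assert len(events) == 1
        ev = events[0]
        assert 19.0 <= ev.start_s <= 20.0
        assert 23.0 <= ev.end_s <= 24.0

    @pytest.mark.parametrize("gap_s,n_expected", [(0.5, 1), (1.5, 2)])
    def test_gap_merge_rule(self, gap_s, n_expected):
        # burst SD chosen so ~8 of 20 window samples must be in-burst:
        # the sub-second gap merges, the 1.5 s gap splits
        n = int(60 * FS)
        b1e = int(25 * FS)
        b2s = b1e + int(gap_s * FS)
        bursts = [(b1e - int(2 * FS), b1e, 0.015), (b2s, b2s + int(2 * FS), 0.015)]
        t, acc = _stationary_signal(n, 0.005, bursts, seed=2)
        code = np.zeros(n, np.int8)
        events = detect_gesture_events(magnitude(acc), t, code, FS, GestureConfig())
        assert len(events) == n_expected

    def test_ambulatory_periods_never_emit_events(self):
        n = int(60 * FS)
        rng = np.random.default_rng(3)
        acc = rng.normal(0, 0.2, (n, 3)) + [0, 0, 1.0]  # high-SD "walking" noise
        code = np.full(n, states.AMBULATORY, np.int8)
        events = detect_gesture_events(magnitude(acc), np.arange(n) / FS, code, FS, GestureConfig())
        assert events == []

    def test_events_confined_to_stationary_samples(self):
        n = int(60 * FS)
        t, acc = _stationary_signal(n, 0.005, [(int(28 * FS), int(32 * FS), 0.05)], seed=4)
        code = np.zeros(n, np.int8)
        code[int(30 * FS) :] = states.AMBULATORY  # label flips mid-burst
        events = detect_gesture_events(magnitude(acc), t, code, FS, GestureConfig())
        assert all(ev.end_s <= 30.0 + 1e-9 for ev in events)

    def test_threshold_monotonicity(self):
        n = int(120 * FS)
        t, acc = _stationary_signal(
            n, 0.005, [(int(10 * FS), int(12 * FS), 0.012), (int(50 * FS), int(55 * FS), 0.03)], seed=5
        )
        m = magnitude(acc)
        code = np.zeros(n, np.int8)
        counts = []
        for thr in (0.005, 0.01, 0.02, 0.04):
            cfg = GestureConfig(sd_threshold_g=thr)
            msd = moving_sd(m, t, FS, cfg)
            counts.append(int(np.sum(msd.sd > thr)))
        assert counts == sorted(counts, reverse=True)

    def test_detector_rotation_invariant(self):
        n = int(60 * FS)
        t, acc = _stationary_signal(n, 0.005, [(int(20 * FS), int(24 * FS), 0.05)], seed=6)
        code = np.zeros(n, np.int8)
        base = detect_gesture_events(magnitude(acc), t, code, FS, GestureConfig())
        Q = ortho_group.rvs(3, random_state=0)
        rot = detect_gesture_events(magnitude(acc @ Q.T), t, code, FS, GestureConfig())
        assert [(e.start_s, e.end_s) for e in rot] == [(e.start_s, e.end_s) for e in base]

    def test_events_sorted_and_disjoint(self, sitting_with_bursts):
        _, rec, _, _ = sitting_with_bursts
        code = np.zeros(rec.n_samples, np.int8)
        events = detect_gesture_events(magnitude(rec), rec.time_s, code, FS, GestureConfig())
        assert len(events) > 3
        for a, b in zip(events, events[1:]):
            assert a.end_s <= b.start_s

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            detect_gesture_events(np.ones(40), np.arange(40) / FS, np.zeros(39, np.int8), FS)


class TestPower:
    def test_constant_magnitude_zero(self):
        assert gesture_power(np.full(30, 1.0)) == 0.0

    def test_hand_computed_pair(self):
        assert gesture_power(np.array([0.9, 1.1])) == pytest.approx(0.02)

    def test_degenerate_event_rejected(self):
        with pytest.raises(DegenerateEventError):
            gesture_power(np.array([1.0]))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=3.0, allow_nan=False), min_size=2, max_size=300)
    )
    def test_equals_n_times_population_variance(self, values):
        m = np.array(values)
        assert gesture_power(m) == pytest.approx(m.size * np.var(m), abs=1e-12 * max(1.0, m.size))


class TestDailyCounts:
    def _segments(self, n_days, wear_h=24.0):
        return [DaySegment(d, 0, 0, wear_h) for d in range(n_days)]

    def test_no_events_all_zero(self):
        daily = daily_gesture_counts([], self._segments(3))
        assert daily["count"].tolist() == [0, 0, 0]

    def test_event_before_midnight_counts_in_earlier_day(self):
        from gestwear.gesture import GestureEvent

        ev = [GestureEvent(86399.0, 86401.0, 40, 0.1)]
        daily = daily_gesture_counts(ev, self._segments(2))
        assert daily["count"].tolist() == [1, 0]

    def test_counts_conserve_total(self, rng):
        from gestwear.gesture import GestureEvent

        starts = np.sort(rng.uniform(0, 5 * 86400, 200))
        ev = [GestureEvent(s, s + 2.0, 40, 0.1) for s in starts]
        daily = daily_gesture_counts(ev, self._segments(5))
        assert daily["count"].sum() == 200
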