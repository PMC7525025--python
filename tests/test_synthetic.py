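"""Synthetic schedules, signals and cohort generation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gestwear.errors import ConfigError
from gestwear.gesture import GestureConfig, magnitude, moving_sd
from gestwear.io import write_recording
from gestwear.synthetic import (
    ActivityScheduleEntry,
    CohortConfig,
    SignalModelParams,
    generate_cohort,
    generate_schedule,
    schedule_sample_labels,
    synthesize_signal,
)


class TestSchedule:
    def test_duration_conservation_without_gaps(self):
        p = SignalModelParams(target_monitoring_ratio=1.0)
        sched = generate_schedule(1, p, seed=0)
        assert sum(e.end_s - e.start_s for e in sched) == 86400
        assert all(e.state != "non_wear" for e in sched)

    def test_duration_conservation_with_gaps(self):
        p = SignalModelParams()
        for seed in range(5):
            sched = generate_schedule(3, p, seed=seed)
            assert sum(e.end_s - e.start_s for e in sched) == 3 * 86400
            # contiguous and sorted
            assert all(a.end_s == b.start_s for a, b in zip(sched, sched[1:]))

    def test_monitoring_target_hit_on_average(self):
        p = SignalModelParams()
        wear = [
            sum(e.end_s - e.start_s for e in generate_schedule(1, p, seed=s) if e.state != "non_wear")
            for s in range(50)
        ]
        assert np.mean(wear) == pytest.approx(0.74 * 86400, rel=0.05)

    def test_same_seed_identical(self):
        p = SignalModelParams()
        assert generate_schedule(2, p, seed=9) == generate_schedule(2, p, seed=9)

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(0, SignalModelParams())


class TestSignal:
    def test_pure_lying_down_all_windows_below_threshold(self):
        p = SignalModelParams(gesture_rate_per_h=0.0)
        sched = [ActivityScheduleEntry("lying_down", 0.0, 1800.0)]
        rec, truth = synthesize_signal(sched, p, seed=3)
        assert len(truth) == 0
        msd = moving_sd(magnitude(rec), rec.time_s, 20.0, GestureConfig())
        assert msd.sd.max() < 0.01

    def test_pure_walking_windows_above_threshold(self):
        p = SignalModelParams()
        sched = [ActivityScheduleEntry("walking", 0.0, 600.0)]
        rec, _ = synthesize_signal(sched, p, seed=4)
        msd = moving_sd(magnitude(rec), rec.time_s, 20.0, GestureConfig())
        assert np.mean(msd.sd > 0.01) > 0.99

    def test_noise_free_stationary_magnitude_is_gravity(self):
        p = SignalModelParams(idle_noise_sd_g=0.0, gesture_rate_per_h=0.0)
        for state in ("sitting", "lying_down"):
            rec, _ = synthesize_signal([ActivityScheduleEntry(state, 0.0, 60.0)], p, seed=0)
            np.testing.assert_array_equal(magnitude(rec), 1.0)

    def test_idle_noise_premise_enforced(self):
        with pytest.raises(ConfigError):
            SignalModelParams(idle_noise_sd_g=0.02).validate()
        with pytest.raises(ConfigError):
            SignalModelParams(gesture_amp_sd_g=0.005).validate()

    def test_planted_events_within_stationary_entries(self):
        p = SignalModelParams(gesture_rate_per_h=20.0)
        sched = generate_schedule(1, p, seed=11)
        _, truth = synthesize_signal(sched, p, seed=12)
        stationary = [
            (e.start_s, e.end_s)
            for e in sched
            if e.state in ("sitting", "standing", "lying_down", "hand_work")
        ]
        for row in truth.itertuples():
            assert any(lo <= row.start_s and row.end_s <= hi for lo, hi in stationary)

    def test_planted_count_is_poisson_in_rate_and_time(self):
        rate, hours = 12.0, 0.5
        p = SignalModelParams(gesture_rate_per_h=rate)
        sched = [ActivityScheduleEntry("sitting", 0.0, hours * 3600)]
        counts = [len(synthesize_signal(sched, p, seed=s)[1]) for s in range(100)]
        expected = rate * hours
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_ground_truth_powers_match_signal(self):
        """Recorded per-event power equals the deviation sum over burst samples."""
        p = SignalModelParams(gesture_rate_per_h=10.0)
        sched = [ActivityScheduleEntry("sitting", 0.0, 1800.0)]
        rec, truth = synthesize_signal(sched, p, seed=21)
        m = magnitude(rec)
        for row in truth.itertuples():
            i0 = np.searchsorted(rec.time_s, row.burst_start_s - 1e-9)
            i1 = i0 + row.n_samples
            seg = m[i0:i1]
            assert np.sum((seg - seg.mean()) ** 2) == pytest.approx(row.power_g2, rel=1e-9)

    def test_same_seed_byte_identical_files(self, tmp_path):
        p = SignalModelParams()
        sched = generate_schedule(1, p, seed=5)
        for k in (1, 2):
            rec, _ = synthesize_signal(sched, p, seed=6)
            write_recording(rec, tmp_path / f"r{k}.csv")
        assert (tmp_path / "r1.csv").read_bytes() == (tmp_path / "r2.csv").read_bytes()

    def test_sample_labels_follow_schedule(self):
        sched = [
            ActivityScheduleEntry("walking", 0.0, 60.0),
            ActivityScheduleEntry("non_wear", 60.0, 120.0),
            ActivityScheduleEntry("sitting", 120.0, 180.0),
        ]
        p = SignalModelParams(target_monitoring_ratio=1.0)
        rec, _ = synthesize_signal(sched, p, seed=0)
        fine, binary = schedule_sample_labels(sched, rec.time_s)
        assert set(binary[rec.time_s < 60.0]) == {1}
        assert set(binary[rec.time_s >= 120.0]) == {0}
        assert not np.any((rec.time_s >= 60.0) & (rec.time_s < 120.0))  # gap has no samples


class TestCohort:
    def test_zero_coupling_yields_null_correlations(self):
        cfg = CohortConfig(n_patients=200, latent_coupling={}, seed=1)
        c = generate_cohort(cfg)
        r = spearmanr(c.patients["gesture_rate_per_h"], c.scores["bnss_total"]).statistic
        assert abs(r) < 0.15

    def test_planted_coupling_recovered(self):
        cfg = CohortConfig(
            n_patients=200,
            latent_coupling={("gesture_rate", "bnss_total"): -0.6},
            seed=2,
        )
        c = generate_cohort(cfg)
        r = spearmanr(c.patients["gesture_rate_per_h"], c.scores["bnss_total"]).statistic
        assert -0.7 <= r <= -0.5

    def test_scores_within_configured_ranges(self):
        c = generate_cohort(CohortConfig(n_patients=33, seed=3))
        assert len(c.scores) == 33
        for key, (lo, hi) in c.config.score_ranges.items():
            assert c.scores[key].between(lo, hi).all()

    def test_infeasible_coupling_rejected(self):
        cfg = CohortConfig(
            latent_coupling={
                ("gesture_rate", "bnss_total"): 0.95,
                ("gesture_rate", "high_effort"): 0.95,
                ("bnss_total", "high_effort"): -0.95,
            }
        )
        with pytest.raises(ConfigError, match="positive semi-definite"):
            generate_cohort(cfg)

    def test_effort_probability_monotone_in_motivation_latent(self):
        c = generate_cohort(CohortConfig(n_patients=200, seed=4))
        tab = c.cohort_table()
        merged = tab.merge(c.patients, on="patient_id")
        r = spearmanr(merged["p_high_effort_base"], merged["high_effort_pct"]).statistic
        assert r > 0.7

    def test_determinism(self):
        a = generate_cohort(CohortConfig(n_patients=10, seed=5))
        b = generate_cohort(CohortConfig(n_patients=10, seed=5))
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigError):
            generate_cohort(CohortConfig(n_patients=2))
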