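"""Simulator contracts: schedule geometry, deviation physics, noise model."""

import numpy as np
import pandas as pd
import pytest

from actscreen import (
    SimulationConfig,
    make_schedule,
    simulate_cohort,
    simulate_recording,
)
from actscreen.exceptions import ConfigError


class TestSchedule:
    def test_fixed_dwell_yields_two_alternating_intervals(self):
        s = make_schedule(10.0, (5.0, 5.0), seed=42)
        assert len(s.intervals) == 2
        assert [iv.eye for iv in s.intervals] == ["left", "right"]
        for iv in s.intervals:
            assert iv.end_s - iv.start_s == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_dwells_within_range_and_tile_duration(self, seed):
        s = make_schedule(10.0, (3.0, 6.0), seed=seed)
        prev_end = 0.0
        prev_eye = None
        for iv in s.intervals:
            assert 3.0 - 1e-9 <= iv.end_s - iv.start_s <= 6.0 + 1e-9
            assert iv.start_s == pytest.approx(prev_end)
            assert iv.eye != prev_eye
            prev_end = iv.end_s
            prev_eye = iv.eye
        assert prev_end == pytest.approx(10.0)

    def test_same_seed_same_schedule(self):
        a = make_schedule(10.0, (3.0, 6.0), seed=7)
        b = make_schedule(10.0, (3.0, 6.0), seed=7)
        assert a == b

    @pytest.mark.parametrize("bad", [(0.0, 5.0), (3.0, 11.0), (6.0, 3.0)])
    def test_invalid_dwell_range_rejected(self, bad):
        with pytest.raises(ConfigError):
            make_schedule(10.0, bad, seed=0)


class TestSimulationConfig:
    def test_amplitude_zero_iff_normal(self):
        with pytest.raises(ConfigError):
            SimulationConfig(condition="normal", deviation_amplitude=0.1)
        with pytest.raises(ConfigError):
            SimulationConfig(condition="exotropia", deviation_amplitude=0.0)

    def test_invalid_prob_bounds(self):
        with pytest.raises(ConfigError):
            SimulationConfig(invalid_frame_prob=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(invalid_frame_prob=-0.1)


class TestRecording:
    def test_frame_count_and_monotone_timestamps(self):
        rec = simulate_recording(SimulationConfig(), seed=1)
        assert rec.n_frames == 600
        assert (np.diff(rec.frames["Timestamp"]) > 0).all()

    def test_normal_zero_noise_constant_difference(self):
        cfg = SimulationConfig(noise_sd=0.0, invalid_frame_prob=0.0)
        rec = simulate_recording(cfg, seed=2)
        diff = rec.frames["RPCX"] - rec.frames["LPCX"]
        assert diff.nunique() == 1
        assert diff.iloc[0] == pytest.approx(
            cfg.baseline_rpcx - cfg.baseline_lpcx)

    def test_instant_deviation_mean_matches_amplitude(self):
        """With both time constants -> 0, the occluded-frame average of the
        centered difference signal equals the amplitude exactly (oracle:
        average the emitted signal over the schedule's occlusion mask)."""
        cfg = SimulationConfig(
            condition="exotropia", deviation_amplitude=0.08,
            noise_sd=0.0, invalid_frame_prob=0.0,
            deviation_onset_tau_s=0.0, deviation_offset_tau_s=0.0,
        )
        rec = simulate_recording(cfg, seed=3)
        t = rec.frames["Timestamp"].to_numpy()
        occluded = rec.schedule.occluded_mask(t)
        diff = (rec.frames["RPCX"] - rec.frames["LPCX"]).to_numpy()
        baseline = cfg.baseline_rpcx - cfg.baseline_lpcx
        assert (diff[occluded] - baseline).mean() == pytest.approx(0.08)
        if (~occluded).any():
            assert (diff[~occluded] - baseline).mean() == pytest.approx(0.0)

    @pytest.mark.parametrize("condition,sign", [("exotropia", 1),
                                                ("esotropia", -1)])
    def test_deviation_sign_over_many_seeds(self, condition, sign):
        """Mean deviation relative to the baseline separation is positive for
        exotropia and negative for esotropia (amplitude >= 3x noise sd)."""
        cfg = SimulationConfig(condition=condition, deviation_amplitude=0.06,
                               noise_sd=0.02)
        for seed in range(100):
            rec = simulate_recording(cfg, seed=seed)
            diff = (rec.frames["RPCX"] - rec.frames["LPCX"]).to_numpy()
            baseline = cfg.baseline_rpcx - cfg.baseline_lpcx
            assert sign * (diff.mean() - baseline) > 0

    def test_validity_rate_converges_to_invalid_prob(self):
        p = 0.1
        cfg = SimulationConfig(invalid_frame_prob=p)
        rec = simulate_recording(cfg, seed=4)
        rate = (rec.frames["LPV"] == 0).mean()
        # binomial 4-sigma band at n = 600
        tol = 4 * np.sqrt(p * (1 - p) / 600)
        assert abs(rate - p) < tol

    def test_invalid_frames_hold_last_valid_coordinates(self):
        cfg = SimulationConfig(invalid_frame_prob=0.2, noise_sd=0.01)
        rec = simulate_recording(cfg, seed=5)
        f = rec.frames
        invalid = np.flatnonzero(f["LPV"].to_numpy() == 0)
        invalid = invalid[invalid > 0]
        assert len(invalid) > 0
        for i in invalid[:20]:
            j = i - 1
            while f["LPV"].iloc[j] == 0 and j > 0:
                j -= 1
            assert f["LPCX"].iloc[i] == f["LPCX"].iloc[j]

    def test_determinism_identical_frames(self):
        cfg = SimulationConfig(condition="esotropia", deviation_amplitude=0.07)
        a = simulate_recording(cfg, seed=9)
        b = simulate_recording(cfg, seed=9)
        pd.testing.assert_frame_equal(a.frames, b.frames)
        assert a.schedule == b.schedule


class TestCohort:
    def test_cohort_composition_and_sample_counts(self):
        cohort = simulate_cohort(25, 18, 7, 0, (3, 7), seed=10)
        m = cohort.manifest
        assert m["participant_id"].nunique() == 50
        per = m.groupby("participant_id")["sample_id"].count()
        assert per.between(3, 7).all()
        by_cond = m.drop_duplicates("participant_id")["condition"].value_counts()
        assert by_cond["normal"] == 25
        assert by_cond["exotropia"] == 18
        assert by_cond["esotropia"] == 7

    def test_single_participant_cohort(self):
        cohort = simulate_cohort(1, 0, 0, 0, (3, 3), seed=0)
        assert len(cohort.recordings) == 3
        assert all(r.condition == "normal" for r in cohort.recordings)
        assert len({r.participant_id for r in cohort.recordings}) == 1

    def test_cohort_determinism(self):
        a = simulate_cohort(2, 2, 1, 1, (3, 4), seed=21)
        b = simulate_cohort(2, 2, 1, 1, (3, 4), seed=21)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for ra, rb in zip(a.recordings, b.recordings):
            pd.testing.assert_frame_equal(ra.frames, rb.frames)

    def test_hypertropia_deviates_vertically(self):
        cohort = simulate_cohort(0, 0, 0, 2, (3, 3), seed=3,
                                 base_config=None)
        rec = cohort.recordings[0]
        y_spread = (rec.frames["LPCY"] - rec.frames["RPCY"]).std()
        assert rec.condition == "hypertropia"
        assert y_spread > 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(0, 0, 0, 0)
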