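"""Preprocessing stages: exact small-case behavior, brute-force oracles,
stage-order enforcement, and class separation on clean signals."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actscreen import (
    DeviationSeries,
    PreprocessConfig,
    SimulationConfig,
    center_signal,
    compress,
    difference_signal,
    featurize,
    fill_invalid,
    raw_features,
    read_recording,
    remove_outliers,
    run_pipeline,
    simulate_recording,
)
from actscreen.exceptions import (
    ConfigError,
    StageOrderError,
    UnrecoverableSampleError,
)


def series(values, mask=None, stage="raw"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    return DeviationSeries(values, mask, stage=stage)


class TestDifferenceSignal:
    def test_reference_row_difference(self):
        log = ("Timestamp,LPCX,LPCY,RPCX,RPCY,LPV,RPV\n"
               "0.00000,0.62102,0.39483,1.00578,0.30799,1,1\n"
               "0.01619,0.62102,0.39483,1.00578,0.30799,0,1\n")
        rec = read_recording(io.StringIO(log))
        s = difference_signal(rec)
        assert s.values[0] == pytest.approx(1.00578 - 0.62102)
        assert s.values[0] == pytest.approx(0.38476)
        assert s.mask[0] and not s.mask[1]
        assert s.stage == "raw"

    def test_identical_eyes_give_zero_series(self):
        cfg = SimulationConfig(noise_sd=0.0, invalid_frame_prob=0.0,
                               baseline_lpcx=0.7, baseline_rpcx=0.7)
        s = difference_signal(simulate_recording(cfg, seed=0))
        assert np.allclose(s.values, 0.0)


class TestFillInvalid:
    def test_linear_midpoint(self):
        s = fill_invalid(series([1.0, 0.0, 3.0], [True, False, True]))
        np.testing.assert_allclose(s.values, [1.0, 2.0, 3.0])
        assert s.mask.all() and s.stage == "filled"

    def test_edges_take_nearest_valid(self):
        s = fill_invalid(series([9.0, 2.0, 9.0], [False, True, False]))
        np.testing.assert_allclose(s.values, [2.0, 2.0, 2.0])

    def test_no_invalid_is_identity(self):
        s = fill_invalid(series([1.0, 2.0]))
        np.testing.assert_allclose(s.values, [1.0, 2.0])

    def test_drop_policy_removes_points(self):
        s = fill_invalid(series([1.0, 5.0, 3.0], [True, False, True]), "drop")
        np.testing.assert_allclose(s.values, [1.0, 3.0])

    def test_all_invalid_unrecoverable(self):
        with pytest.raises(UnrecoverableSampleError):
            fill_invalid(series([1.0, 2.0], [False, False]))


class TestCenterSignal:
    def test_constant_maps_to_zero(self):
        s = center_signal(series([0.4, 0.4, 0.4], stage="filled"))
        np.testing.assert_allclose(s.values, 0.0)

    def test_median_subtraction(self):
        s = center_signal(series([0.38, 0.38, 0.42], stage="filled"))
        np.testing.assert_allclose(s.values, [0.0, 0.0, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_output_median_is_zero(self, seed):
        rng = np.random.default_rng(seed)
        s = center_signal(series(rng.normal(0.4, 0.1, 101), stage="filled"))
        assert np.median(s.values) == pytest.approx(0.0, abs=1e-12)


class TestRemoveOutliers:
    def test_jump_rule_small_case(self):
        s = remove_outliers(series([0, 0, 0.5, 0, 0], stage="centered"),
                            threshold=0.025)
        np.testing.assert_allclose(s.values, [0, 0, 0])

    @pytest.mark.parametrize("mode", ["frame_jump", "deviation_from_mean"])
    def test_constant_series_unchanged(self, mode):
        s = remove_outliers(series([0.1] * 7, stage="centered"), mode=mode)
        np.testing.assert_allclose(s.values, 0.1)

    def test_mean_deviation_mode(self):
        s = remove_outliers(series([0.0, 0.0, 1.0], stage="centered"),
                            threshold=0.5, mode="deviation_from_mean")
        # mean = 1/3; only the 1.0 point is farther than 0.5 from it
        np.testing.assert_allclose(s.values, [0.0, 0.0])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_reference(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 0.03, 200)
        out = remove_outliers(series(vals, stage="centered"), 0.025).values
        ref = [vals[0]]
        for t in range(1, len(vals)):
            if abs(vals[t] - vals[t - 1]) <= 0.025:
                ref.append(vals[t])
        np.testing.assert_allclose(out, ref)

    def test_everything_dropped_unrecoverable(self):
        with pytest.raises(UnrecoverableSampleError):
            remove_outliers(series([0.0, 1.0], stage="centered"),
                            threshold=0.025, mode="deviation_from_mean")


class TestCompress:
    def test_exact_division(self):
        s = compress(series(np.arange(600.0), stage="filtered"), 10)
        assert len(s) == 60
        assert s.stage == "compressed"

    def test_constant_preserved(self):
        s = compress(series([0.3] * 40, stage="filtered"), 10)
        np.testing.assert_allclose(s.values, 0.3)

    @pytest.mark.parametrize("n,w", [(600, 10), (57, 10), (53, 10), (7, 3)])
    def test_matches_windowed_mean_reference(self, n, w):
        rng = np.random.default_rng(n * 31 + w)
        vals = rng.normal(size=n)
        out = compress(series(vals, stage="filtered"), w).values
        ref = [vals[i * w:(i + 1) * w].mean() for i in range(n // w)]
        rem = n % w
        if rem >= w / 2:
            ref.append(vals[n - rem:].mean())
        np.testing.assert_allclose(out, ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 300), w=st.integers(1, 20))
    def test_length_contract(self, n, w):
        vals = np.zeros(n)
        rem = n % w
        expected = n // w + (1 if rem >= w / 2 else 0)
        if expected == 0:
            with pytest.raises(UnrecoverableSampleError):
                compress(series(vals, stage="filtered"), w)
        else:
            assert len(compress(series(vals, stage="filtered"), w)) == expected

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigError):
            compress(series([1.0, 2.0], stage="filtered"), 0)


class TestFeaturize:
    def test_same_length_is_identity(self):
        vals = np.linspace(-1, 1, 60)
        out = featurize(series(vals, stage="compressed"), 60)
        np.testing.assert_allclose(out, vals)

    def test_constant_any_length(self):
        out = featurize(series([0.2] * 33, stage="compressed"), 60)
        np.testing.assert_allclose(out, 0.2)

    def test_linear_ramp_endpoints_preserved(self):
        out = featurize(series(np.linspace(0, 1, 120), stage="compressed"), 60)
        assert out[0] == pytest.approx(0.0)
        assert out[-1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diff(out), np.diff(out)[0])

    def test_too_short_rejected(self):
        with pytest.raises(UnrecoverableSampleError):
            featurize(series([1.0], stage="compressed"), 60)


class TestStageOrder:
    def test_out_of_order_application_raises(self):
        raw = series([1.0, 2.0, 3.0])
        with pytest.raises(StageOrderError):
            center_signal(raw)  # must be filled first
        with pytest.raises(StageOrderError):
            remove_outliers(raw)
        with pytest.raises(StageOrderError):
            compress(raw)
        with pytest.raises(StageOrderError):
            featurize(raw)
        filled = fill_invalid(raw)
        with pytest.raises(StageOrderError):
            fill_invalid(filled)


def _hand_pipeline(rec, cfg):
    """Independent by-hand restatement of the pipeline on one recording."""
    f = rec.frames
    vals = (f["RPCX"] - f["LPCX"]).to_numpy()
    valid = (f["LPV"].to_numpy() == 1) & (f["RPV"].to_numpy() == 1)
    idx = np.arange(len(vals))
    vals = np.interp(idx, idx[valid], vals[valid])
    vals = vals - np.median(vals)
    kept = [vals[0]]
    for t in range(1, len(vals)):
        if abs(vals[t] - vals[t - 1]) <= cfg.outlier_threshold:
            kept.append(vals[t])
    vals = np.asarray(kept)
    w = cfg.compression_window
    out = [vals[i * w:(i + 1) * w].mean() for i in range(len(vals) // w)]
    if len(vals) % w >= w / 2:
        out.append(vals[len(vals) - len(vals) % w:].mean())
    vals = np.asarray(out)
    return np.interp(np.linspace(0, len(vals) - 1, cfg.feature_length),
                     np.arange(len(vals)), vals)


class TestPipeline:
    def test_zero_noise_normal_is_flat(self):
        cfg = SimulationConfig(noise_sd=0.0, invalid_frame_prob=0.0)
        feat = run_pipeline(simulate_recording(cfg, seed=0))
        np.testing.assert_allclose(feat, 0.0, atol=1e-12)

    def test_matches_hand_applied_stages(self, clean_exo_config):
        rec = simulate_recording(clean_exo_config, seed=6)
        cfg = PreprocessConfig()
        np.testing.assert_allclose(run_pipeline(rec, cfg),
                                   _hand_pipeline(rec, cfg))

    def test_noisy_recording_matches_hand_applied_stages(self):
        cfg_sim = SimulationConfig(condition="esotropia",
                                   deviation_amplitude=0.09,
                                   invalid_frame_prob=0.05)
        rec = simulate_recording(cfg_sim, seed=7)
        cfg = PreprocessConfig()
        np.testing.assert_allclose(run_pipeline(rec, cfg),
                                   _hand_pipeline(rec, cfg))

    def test_all_invalid_recording_unrecoverable(self):
        cfg = SimulationConfig(noise_sd=0.0, invalid_frame_prob=0.0)
        rec = simulate_recording(cfg, seed=1)
        frames = rec.frames.copy()
        frames["LPV"] = 0
        frames["RPV"] = 0
        from actscreen.simulate import GazeRecording

        bad = GazeRecording(frames=frames)
        with pytest.raises(UnrecoverableSampleError):
            run_pipeline(bad)

    @pytest.mark.parametrize("condition,sign",
                             [("exotropia", 1), ("esotropia", -1)])
    def test_signed_extremum_separates_classes(self, condition, sign):
        """On zero-noise simulations the feature vector's signed extremum is
        positive for exotropia, negative for esotropia, ~0 for normal."""
        cfg = SimulationConfig(condition=condition, deviation_amplitude=0.1,
                               noise_sd=0.0, invalid_frame_prob=0.0)
        for seed in range(20):
            feat = run_pipeline(simulate_recording(cfg, seed=seed))
            extremum = feat[np.argmax(np.abs(feat))]
            assert sign * extremum > 0

    def test_raw_features_keep_baseline_offset(self, clean_exo_config):
        rec = simulate_recording(clean_exo_config, seed=2)
        raw = raw_features(rec)
        baseline = (clean_exo_config.baseline_rpcx
                    - clean_exo_config.baseline_lpcx)
        assert raw.min() >= baseline - 1e-9
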