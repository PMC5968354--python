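import numpy as np
import pytest

import beatvar as bv
from beatvar.beat_detection import (
    IntervalSeries,
    align_lag,
    compute_bbi,
    detect_beats,
    detect_beats_electrical,
    estimate_threshold,
    moving_average,
)
from beatvar.synthetic_data import gen_electrode_trace
from beatvar.trace_extraction import GrayTrace


def _dip_trace(centers, depth=30.0, baseline=100.0, half=20, n=1500):
    """Triangular dips at given centers on a flat baseline."""
    x = np.full(n, baseline)
    for c in centers:
        for d in range(-half, half + 1):
            x[c + d] = min(x[c + d], baseline - depth * (1 - abs(d) / half))
    return GrayTrace(x, 1000.0)


class TestMovingAverage:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 42.0)
        np.testing.assert_array_equal(moving_average(x, 25), x)

    def test_impulse_window3(self):
        out = moving_average(np.array([0.0, 0, 1, 0, 0]), 3)
        np.testing.assert_allclose(out, [0, 1 / 3, 1 / 3, 1 / 3, 0])

    def test_matches_naive_loop_with_truncated_edges(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 255, 200)
        out = moving_average(x, 25)
        for i in range(x.size):
            lo, hi = max(0, i - 12), min(x.size, i + 13)
            assert out[i] == pytest.approx(x[lo:hi].mean(), abs=1e-9)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 0)
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 11)


class TestEstimateThreshold:
    def test_midpoint_arithmetic(self):
        # baseline 100, noise SD ~1, deepest excursion 60
        rng = np.random.default_rng(5)
        x = 100.0 + rng.normal(0, 1.0, 5000)
        x[2500] = 60.0
        thr = estimate_threshold(x)
        assert thr == pytest.approx(((100 - 2 * 1.0) + 60) / 2, abs=0.3)

    def test_flat_trace_raises(self):
        with pytest.raises(ValueError, match="no contractions"):
            estimate_threshold(np.full(100, 100.0))

    def test_threshold_inside_admissible_interval(self, default_run):
        cfg, gt, trace, _ = default_run
        smoothed = moving_average(trace.values, 25)
        thr = estimate_threshold(smoothed)
        assert smoothed.min() < thr < np.median(smoothed) - 2 * (cfg.noise_sd / 5)


class TestDetectBeats:
    def test_two_clean_dips_found_exactly(self):
        trace = _dip_trace([500, 1000])
        beats = detect_beats(trace, window=25)
        assert list(beats.indices) == [500, 1000]

    def test_plateau_tie_takes_second_sample(self):
        # force an exact two-sample tie in the smoothed signal via symmetry:
        # a flat-bottom dip whose smoothed minimum spans indices i and i+1
        x = np.full(400, 100.0)
        x[190:212] = 50.0  # 22-sample flat bottom, even => two-sample smoothed tie
        beats = detect_beats(GrayTrace(x, 1000.0), window=25, threshold=80.0)
        sm = moving_average(x, 25)
        run = np.flatnonzero(sm < 80.0)
        seg = sm[run[0] : run[-1] + 1]
        ties = np.flatnonzero(seg == seg.min()) + run[0]
        assert ties.size >= 2  # construction gives an exact tie
        assert beats.indices[0] == ties[-1]

    def test_ground_truth_recovery_at_defaults(self, default_run):
        cfg, gt, trace, beats = default_run
        assert len(beats) == len(gt.indices)
        assert np.abs(beats.indices - gt.indices).max() <= 1

    def test_no_sample_below_threshold_gives_empty_series(self):
        x = np.full(200, 100.0) + np.sin(np.arange(200) / 10)
        beats = detect_beats(GrayTrace(x, 1000.0), threshold=50.0)
        assert len(beats) == 0

    def test_threshold_above_baseline_raises(self):
        trace = _dip_trace([500, 1000])
        with pytest.raises(ValueError, match="baseline"):
            detect_beats(trace, threshold=150.0)

    def test_partial_dip_at_trace_end_discarded(self):
        trace = _dip_trace([500])
        cut = GrayTrace(trace.values[:510], 1000.0)  # dip still below thr at end
        beats = detect_beats(cut, threshold=85.0)
        assert len(beats) == 0

    def test_bbi_invariant_to_constant_offset(self, default_run):
        cfg, gt, trace, beats = default_run
        shifted = GrayTrace(trace.values + 30.0, trace.sample_rate)
        beats2 = detect_beats(shifted)
        np.testing.assert_array_equal(beats.indices, beats2.indices)
        np.testing.assert_allclose(
            compute_bbi(beats).bbi, compute_bbi(beats2).bbi, atol=1e-12
        )


class TestComputeBbi:
    def test_interval_arithmetic(self):
        beats = bv.BeatSeries(
            indices=[100, 600, 1100],
            times=[0.100, 0.600, 1.100],
            minima_values=[80, 80, 80],
            threshold_used=90.0,
        )
        np.testing.assert_allclose(compute_bbi(beats).bbi, [500.0, 500.0])

    def test_661_beats_give_660_intervals(self):
        idx = np.arange(661) * 512
        beats = bv.BeatSeries(idx, idx / 1000.0, np.full(661, 80.0), 90.0)
        assert len(compute_bbi(beats)) == 660

    def test_single_beat_raises(self):
        beats = bv.BeatSeries([5], [0.005], [80.0], 90.0)
        with pytest.raises(ValueError):
            compute_bbi(beats)

    def test_positive_interval_invariant(self):
        with pytest.raises(ValueError):
            IntervalSeries(np.array([500.0, -1.0]))


class TestElectrical:
    def test_clean_spikes_detected_at_constant_offset(self):
        cfg = bv.SimConfig(n_beats=40, seed=9)
        gt = bv.gen_beat_train(cfg)
        v = gen_electrode_trace(gt)
        beats = detect_beats_electrical(v, 1000.0, threshold=0.5)
        assert len(beats) == 40
        offsets = beats.indices - gt.indices
        assert np.all(offsets == offsets[0])  # same crossing sample every beat

    def test_derivative_mode_with_noise_no_duplicates(self):
        cfg = bv.SimConfig(n_beats=40, seed=9)
        gt = bv.gen_beat_train(cfg)
        v = gen_electrode_trace(gt, noise_sd=0.02, rng=np.random.default_rng(1))
        beats = detect_beats_electrical(v, 1000.0, threshold=300.0, mode="derivative")
        assert len(beats) == 40
        assert np.diff(beats.indices).min() > 50  # refractory window respected

    def test_threshold_below_global_min_gives_empty(self):
        cfg = bv.SimConfig(n_beats=10, seed=2)
        v = gen_electrode_trace(bv.gen_beat_train(cfg))
        beats = detect_beats_electrical(v, 1000.0, threshold=v.min() - 1.0)
        assert len(beats) == 0


class TestAlignLag:
    def test_identical_series_lag_zero(self):
        rng = np.random.default_rng(3)
        a = IntervalSeries(500 + rng.normal(0, 20, 50))
        lag, ta, tb = align_lag(a, IntervalSeries(a.bbi.copy()))
        assert lag == 0
        assert len(ta) == len(a)

    def test_known_delay_recovered_with_overlap(self):
        rng = np.random.default_rng(4)
        base = 500 + rng.normal(0, 25, 60)
        a = IntervalSeries(base)
        b = IntervalSeries(base[2:])
        lag, ta, tb = align_lag(a, b)
        assert lag == 2
        assert len(ta) == len(a) - 2
        np.testing.assert_allclose(ta.bbi, tb.bbi)

    def test_noisy_lag3_recovered(self):
        rng = np.random.default_rng(8)
        base = 500 + rng.normal(0, 25, 80)
        b = IntervalSeries(base[3:] + rng.normal(0, 2, 77))
        lag, *_ = align_lag(IntervalSeries(base), b)
        assert lag == 3

    def test_constant_series_degenerate(self):
        a = IntervalSeries(np.full(20, 500.0))
        with pytest.raises(ValueError, match="degenerate"):
            align_lag(a, a)


class TestOptoElectricalAgreement:
    def test_paired_bbi_regression_slope_near_unity(self):
        """Mirrors the validation of optical against electrode intervals."""
        cfg = bv.SimConfig(n_beats=120, seed=17)
        gt = bv.gen_beat_train(cfg)
        trace, _ = bv.gen_gray_trace(gt)
        optical = compute_bbi(detect_beats(trace))
        v = gen_electrode_trace(gt, noise_sd=0.02, rng=np.random.default_rng(6))
        electrical = compute_bbi(detect_beats_electrical(v, 1000.0, threshold=0.5))
        lag, ta, tb = align_lag(electrical, optical)
        slope = np.polyfit(ta.bbi, tb.bbi, 1)[0]
        r2 = np.corrcoef(ta.bbi, tb.bbi)[0, 1] ** 2
        assert 0.95 <= slope <= 1.05
        assert r2 >= 0.98
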