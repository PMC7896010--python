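"""Conditional averaging, conditioning curves, significance, linear prediction."""

import numpy as np
import pytest

from renshaw.coherence import CoherenceConfig
from renshaw.errors import ConfigurationError, InsufficientDataError, SupportError
from renshaw.nonlinearity import (
    ConditioningCurve,
    ConditioningWindow,
    CurvePoint,
    conditional_average_corrected,
    conditioning_curve,
    curve_significance,
    linear_prediction_coherence,
    long_range_windows,
    select_conditioned_triggers,
)
from renshaw.signal_prep import TriggeredAverage, triggered_average
from renshaw.synthetic import (
    IPSPKernel,
    NonlinearityConfig,
    RecordingConfig,
    StimulusTrain,
    TrainConfig,
    generate_poisson_train,
    synthesize_recording,
)

FS = 25000.0


def _train(times_s, duration):
    return StimulusTrain("n1", np.asarray(times_s), TrainConfig(duration=duration))


class TestSelectConditionedTriggers:
    def test_hand_worked_example(self):
        # times 10, 12, 50, 300, 303 ms; window [0, 5) ms
        tr = _train([0.010, 0.012, 0.050, 0.300, 0.303], 1.0)
        got = select_conditioned_triggers(tr, ConditioningWindow(0.0, 0.005))
        assert [(round(t, 4), round(l, 4)) for t, l in got] == [
            (0.012, 0.002), (0.303, 0.003)
        ]

    def test_window_beyond_any_interval_is_empty(self):
        tr = _train([0.1, 0.2, 0.3], 1.0)
        assert select_conditioned_triggers(tr, ConditioningWindow(5.0, 0.5)) == []

    def test_exhaustive_pairwise_oracle_on_poisson_train(self):
        train = generate_poisson_train(TrainConfig(duration=50.0, seed=8), "n1")
        w = ConditioningWindow(0.010, 0.005)
        got = dict(select_conditioned_triggers(train, w, exclude_intervening=True))
        times = train.times
        expected = {}
        for i, T in enumerate(times):
            cands = [
                (j, T - times[j])
                for j in range(i)
                if w.offset <= T - times[j] < w.offset + w.width
            ]
            if not cands:
                continue
            j, lag = cands[-1]  # most recent qualifying conditioner
            if j == i - 1:  # no intervening stimulus
                expected[float(T)] = float(lag)
        assert got == pytest.approx(expected)

    def test_intervening_stimuli_kept_when_flag_off(self):
        tr = _train([0.0, 0.005, 0.012], 1.0)
        w = ConditioningWindow(0.010, 0.005)
        assert select_conditioned_triggers(tr, w, exclude_intervening=True) == []
        kept = select_conditioned_triggers(tr, w, exclude_intervening=False)
        assert kept == [pytest.approx((0.012, 0.012))]

    def test_selected_fraction_matches_interval_distribution(self):
        # P(interval in [3,5) ms) for dead-time-shifted exponential intervals
        cfg = TrainConfig(duration=2000.0, mean_rate=10.0, dead_time=0.003, seed=3)
        train = generate_poisson_train(cfg)
        sel = select_conditioned_triggers(train, ConditioningWindow(0.0, 0.005))
        lam = 1.0 / (1.0 / cfg.mean_rate - cfg.dead_time)
        p = 1.0 - np.exp(-lam * 0.002)
        frac = len(sel) / (len(train) - 1)
        se = np.sqrt(p * (1 - p) / len(train))
        assert abs(frac - p) < 4 * se


class TestConditionalAverageCorrected:
    @staticmethod
    def _isolated_pair_recording(lag_s, depression):
        """Widely separated (C, T) pairs; T scaled by a known factor."""
        kern = IPSPKernel(amplitude_uv=300.0)
        nl = NonlinearityConfig(
            short_depression_max=depression, short_recovery_tau=lag_s / 1.0,
            low_rate_depression_max=0.0,
        )
        pairs = np.arange(0.5, 60.0, 0.5)
        times = np.sort(np.concatenate([pairs, pairs + lag_s]))
        train = StimulusTrain("n1", times, TrainConfig(duration=61.0))
        cfg = RecordingConfig(
            kernels={"n1": kern}, noise_sd_uv=0.0, artifact_amplitude_uv=0.0,
            field_amplitude_uv=0.0, nonlinearity=nl, seed=0,
        )
        return synthesize_recording(cfg, [train]), train, kern

    def test_zero_noise_algebraic_identity(self):
        """Corrected average equals factor x kernel exactly for isolated pairs."""
        lag = 0.008
        rec, train, kern = self._isolated_pair_recording(lag, depression=0.5)
        factor = 1.0 - 0.5 * np.exp(-1.0)
        # the true single-stimulus response serves as the all-stimulus average
        lags = np.arange(-int(0.02 * FS), int(0.2 * FS)) / FS
        all_avg = TriggeredAverage(
            lags, rec.truth.resting_mv + kern.waveform(lags), 100,
            rec.truth.resting_mv, (-0.02, -0.002), FS,
        )
        sel = select_conditioned_triggers(train, ConditioningWindow(0.0, 0.016))
        assert len(sel) > 50
        cond = conditional_average_corrected(rec.intracellular, sel, all_avg, FS)
        expected = factor * kern.waveform(cond.lags)
        err = np.max(np.abs((cond.mean - cond.baseline) - expected))
        assert err < 1e-9 * kern.amplitude_uv / 1000.0

    def test_ground_truth_depression_factor_recovered(self):
        rec, train, kern = self._isolated_pair_recording(0.008, depression=1.0)
        # factor = 1 - 1.0*exp(-1) = 0.6321 at one recovery time constant
        lags = np.arange(-int(0.02 * FS), int(0.2 * FS)) / FS
        all_avg = TriggeredAverage(
            lags, rec.truth.resting_mv + kern.waveform(lags), 100,
            rec.truth.resting_mv, (-0.02, -0.002), FS,
        )
        sel = select_conditioned_triggers(train, ConditioningWindow(0.0, 0.016))
        cond = conditional_average_corrected(rec.intracellular, sel, all_avg, FS)
        ratio = (cond.baseline - cond.mean.min()) / (kern.amplitude_uv / 1000.0)
        # grid-sampled extremum sits within one sample of the analytic peak
        assert ratio == pytest.approx(1.0 - np.exp(-1.0), abs=1e-4)

    def test_shift_beyond_support_raises(self):
        rec, train, kern = self._isolated_pair_recording(0.008, 0.0)
        lags = np.arange(-int(0.02 * FS), int(0.01 * FS)) / FS  # short support
        all_avg = TriggeredAverage(
            lags, rec.truth.resting_mv + kern.waveform(lags), 100,
            rec.truth.resting_mv, (-0.02, -0.002), FS,
        )
        sel = select_conditioned_triggers(train, ConditioningWindow(0.0, 0.016))
        with pytest.raises(SupportError):
            conditional_average_corrected(rec.intracellular, sel, all_avg, FS)

    def test_empty_selection_raises(self):
        with pytest.raises(InsufficientDataError):
            conditional_average_corrected(
                np.zeros(100), [],
                TriggeredAverage(
                    np.arange(-20, 20) / FS, np.zeros(40), 1, 0.0,
                    (-8e-4, -4e-5), FS,
                ),
                FS,
            )


class TestConditioningCurve:
    def test_linear_recording_stays_near_100_percent(self):
        train = generate_poisson_train(TrainConfig(duration=400.0, seed=11), "n1")
        cfg = RecordingConfig(
            kernels={"n1": IPSPKernel(amplitude_uv=350.0)}, noise_sd_uv=125.0,
            nonlinearity=NonlinearityConfig.linear(), seed=11,
        )
        rec = synthesize_recording(cfg, [train])
        curve = conditioning_curve(rec, "n1")
        df = curve.to_frame().dropna(subset=["amplitude_pct"])
        assert len(df) >= 8
        assert np.all(np.abs(df["amplitude_pct"] - 100.0) <= 3 * df["sem"])

    def test_undetected_unconditioned_ipsp_raises(self):
        train = generate_poisson_train(TrainConfig(duration=60.0, seed=12), "n1")
        cfg = RecordingConfig(
            kernels={"n1": IPSPKernel(amplitude_uv=20.0)}, noise_sd_uv=50.0, seed=12
        )
        rec = synthesize_recording(cfg, [train])
        with pytest.raises(InsufficientDataError, match="not detected"):
            conditioning_curve(rec, "n1")

    def test_long_range_frequency_axis_is_reciprocal_center(self):
        windows = long_range_windows()
        for w in windows:
            assert w.width == pytest.approx(0.100)
        train = generate_poisson_train(TrainConfig(duration=300.0, seed=13), "n1")
        cfg = RecordingConfig(
            kernels={"n1": IPSPKernel(amplitude_uv=350.0)}, noise_sd_uv=100.0,
            nonlinearity=NonlinearityConfig.linear(), seed=13,
        )
        rec = synthesize_recording(cfg, [train])
        curve = conditioning_curve(rec, "n1", windows=windows[:4], axis_mode="frequency")
        for p, w in zip(curve.points, windows[:4]):
            assert p.axis_value == pytest.approx(1.0 / w.center, rel=1e-12)

    def test_low_rate_suppression_minimum_falls_in_5_to_7_hz(self):
        """Low-rate generator suppression shows up as a dip at 5-7 Hz."""
        nl = NonlinearityConfig(
            short_depression_max=0.0,
            low_rate_depression_max=0.4,
            low_rate_center=1.0 / 6.0,
            low_rate_width=0.045,
        )
        train = generate_poisson_train(TrainConfig(duration=900.0, seed=14), "n1")
        cfg = RecordingConfig(
            kernels={"n1": IPSPKernel(amplitude_uv=400.0)}, noise_sd_uv=100.0,
            nonlinearity=nl, seed=14,
        )
        rec = synthesize_recording(cfg, [train])
        curve = conditioning_curve(rec, "n1", axis_mode="frequency", min_triggers=30)
        df = curve.to_frame().dropna(subset=["amplitude_pct"])
        dip_freq = df.loc[df["amplitude_pct"].idxmin(), "axis_value"]
        assert 5.0 <= dip_freq <= 7.0


class TestCurveSignificance:
    @staticmethod
    def _cohort(rng, point_means, n_pairs=14, sd=2.0):
        windows = [ConditioningWindow(0.005 * i, 0.005) for i in range(len(point_means))]
        curves = []
        for _ in range(n_pairs):
            pts = tuple(
                CurvePoint(w, w.center, m + sd * rng.standard_normal(), 100, w.center)
                for w, m in zip(windows, point_means)
            )
            curves.append(ConditioningCurve("n1", "interval", pts, 300.0))
        return curves

    def test_identical_100_percent_accepts_nothing(self):
        curves = self._cohort(np.random.default_rng(0), [100.0] * 8, sd=0.0)
        # zero variance makes t undefined; use tiny jitter instead
        curves = self._cohort(np.random.default_rng(0), [100.0] * 8, sd=1.0)
        df = curve_significance(curves)
        assert not df["accepted"].any()

    def test_power_of_short_lag_depression(self):
        """True 60% depression at short lags is found; null points are not."""
        means = [60.0, 60.0, 60.0] + [100.0] * 5
        hits = np.zeros(8)
        reps = 20
        for r in range(reps):
            curves = self._cohort(np.random.default_rng(100 + r), means, sd=3.0)
            hits += curve_significance(curves)["accepted"].to_numpy()
        assert np.all(hits[:3] >= 0.95 * reps)
        assert np.all(hits[3:] <= 0.05 * reps + 1)

    def test_t_statistic_matches_hand_computation(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        curves = self._cohort(rng, [100.0] * 4, n_pairs=10, sd=4.0)
        df = curve_significance(curves)
        col = np.array([c.points[2].amplitude_pct for c in curves])
        t, p = sps.ttest_1samp(col, 100.0)
        assert df.loc[2, "p"] == pytest.approx(p, rel=1e-12)
        sem = np.std(col, ddof=1) / np.sqrt(len(col))
        assert df.loc[2, "sem"] == pytest.approx(sem, rel=1e-12)
        assert df.loc[2, "err95"] == pytest.approx(2 * sem, rel=1e-12)

    def test_fewer_than_two_curves_raises(self):
        curves = self._cohort(np.random.default_rng(0), [100.0] * 4)
        with pytest.raises(InsufficientDataError):
            curve_significance(curves[:1])


class TestLinearPredictionCoherence:
    @staticmethod
    def _kernel_avg(kern):
        lags = np.arange(-int(0.02 * FS), int(0.08 * FS)) / FS
        return TriggeredAverage(
            lags, -70.0 + kern.waveform(lags), 1000, -70.0, (-0.02, -0.002), FS
        )

    def test_deterministic_linear_map_has_near_unit_coherence(self):
        """Noise-free convolution gives coherence ~1 wherever the kernel's
        transfer magnitude is appreciable (convolution tails crossing the
        non-overlapping window boundaries keep the estimate just below 1)."""
        kern = IPSPKernel(amplitude_uv=300.0)
        train = generate_poisson_train(TrainConfig(duration=60.0, seed=20), "n1")
        cfg = CoherenceConfig(window_len=16384)
        avg = self._kernel_avg(kern)
        spec = linear_prediction_coherence(avg, train, cfg)
        k = kern.waveform(np.arange(int(0.08 * FS)) / FS)
        H = np.abs(np.fft.rfft(k, 16384))[1:]
        strong = H > 0.1 * H.max()
        assert np.all(spec.coh[strong] > 0.95)
        assert spec.coh[strong].mean() > 0.97

    def test_additive_noise_only_reduces_coherence(self):
        kern = IPSPKernel(amplitude_uv=300.0)
        train = generate_poisson_train(TrainConfig(duration=120.0, seed=21), "n1")
        rec_cfg = RecordingConfig(
            kernels={"n1": kern}, noise_sd_uv=150.0, artifact_amplitude_uv=0.0,
            field_amplitude_uv=0.0, nonlinearity=NonlinearityConfig.linear(), seed=21,
        )
        rec = synthesize_recording(rec_cfg, [train])
        cfg = CoherenceConfig(window_len=4096)
        from renshaw.coherence import binarize_train, coherence_spectrum

        n = len(rec.intracellular)
        x = binarize_train(train, FS, n)
        measured = coherence_spectrum(x, rec.intracellular, cfg)
        predicted = linear_prediction_coherence(
            self._kernel_avg(kern), train, cfg, n_samples=n
        )
        assert np.all(measured.coh <= predicted.coh + 0.05)

    @staticmethod
    def _gap_profile(seed, low_rate_max, duration=400.0):
        from renshaw.coherence import binarize_train, coherence_spectrum
        from renshaw.signal_prep import triggered_average as tavg

        nl = NonlinearityConfig(
            short_depression_max=0.6, short_recovery_tau=0.008,
            low_rate_depression_max=low_rate_max,
        )
        kern = IPSPKernel(amplitude_uv=400.0)
        train = generate_poisson_train(TrainConfig(duration=duration, seed=seed), "n1")
        rec_cfg = RecordingConfig(
            kernels={"n1": kern}, noise_sd_uv=50.0, artifact_amplitude_uv=0.0,
            field_amplitude_uv=0.0, nonlinearity=nl, seed=seed,
        )
        rec = synthesize_recording(rec_cfg, [train])
        cfg = CoherenceConfig(window_len=16384)
        n = len(rec.intracellular)
        x = binarize_train(train, FS, n)
        measured = coherence_spectrum(x, rec.intracellular, cfg)
        all_avg = tavg(rec.intracellular, train.times, FS, window=(-0.02, 0.18))
        predicted = linear_prediction_coherence(all_avg, train, cfg, n_samples=n)
        gap = predicted.coh - measured.coh

        def band_mean(lo, hi):
            m = (measured.freqs >= lo) & (measured.freqs <= hi)
            return float(gap[m].mean())

        return band_mean

    def test_nonlinear_generator_gap_is_band_structured(self):
        """Transmission nonlinearities widen the predicted-minus-measured
        coherence gap outside the mid band: paired-pulse depression degrades
        the high frequencies, and switching the 5-7 Hz suppression on raises
        the low-frequency gap far above the matched control without it."""
        gap_on = self._gap_profile(22, low_rate_max=0.5)
        gap_off = self._gap_profile(22, low_rate_max=0.0)
        # high-frequency divergence from paired-pulse depression
        assert gap_on(30, 100) > gap_on(10, 30)
        # low-rate suppression specifically elevates the low band
        assert gap_on(4, 8) > gap_off(4, 8) + 0.01
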