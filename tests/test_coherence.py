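"""Point-process coherence, significance limits, circular phases, delay slope."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renshaw.coherence import (
    CoherenceConfig,
    CoherenceSpectrum,
    average_coherence,
    binarize_train,
    circular_mean_phase,
    coherence_significance,
    coherence_spectrum,
    phase_slope_delay,
    pooled_band_phase,
)
from renshaw.errors import (
    GridError,
    InsufficientDataError,
    UndefinedMeanError,
)
from renshaw.synthetic import StimulusTrain, TrainConfig, generate_poisson_train

FS = 25000.0


def _small_cfg(window_len=1024, alpha=0.05):
    return CoherenceConfig(window_len=window_len, sample_rate=FS, alpha=alpha)


class TestBinarize:
    def test_empty_train_all_zero(self):
        tr = StimulusTrain("n", np.empty(0), TrainConfig(duration=1.0))
        sig = binarize_train(tr, FS, 1000)
        assert sig.sum() == 0

    def test_floor_index_arithmetic(self):
        tr = StimulusTrain("n", np.array([0.0, 0.00012]), TrainConfig(duration=1.0))
        sig = binarize_train(tr, FS, 100)
        assert sig[0] == 1 and sig[3] == 1 and sig.sum() == 2

    def test_sum_equals_event_count_for_protocol_train(self):
        train = generate_poisson_train(TrainConfig(duration=30.0, seed=1))
        sig = binarize_train(train, FS, int(30 * FS))
        assert sig.sum() == len(train)

    def test_event_beyond_end_raises(self):
        tr = StimulusTrain("n", np.array([0.5]), TrainConfig(duration=1.0))
        with pytest.raises(ValueError, match="beyond"):
            binarize_train(tr, FS, 1000)


class TestCoherenceSpectrum:
    def test_self_coherence_is_unity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8 * 1024)
        spec = coherence_spectrum(x, x, _small_cfg())
        np.testing.assert_allclose(spec.coh, 1.0, atol=1e-10)

    def test_independent_noise_mean_coherence_is_one_over_L(self):
        rng = np.random.default_rng(1)
        L = 50
        x = rng.standard_normal(L * 1024)
        y = rng.standard_normal(L * 1024)
        spec = coherence_spectrum(x, y, _small_cfg())
        # E[coh] = 1/L under independence
        assert spec.coh.mean() == pytest.approx(1.0 / L, rel=0.15)

    def test_frequency_resolution_of_standard_window(self):
        assert 25000.0 / 16384.0 == pytest.approx(1.53, abs=0.005)
        cfg = CoherenceConfig()
        assert cfg.resolution == pytest.approx(1.5259, abs=1e-4)

    def test_grid_spacing_matches_config(self):
        rng = np.random.default_rng(2)
        spec = coherence_spectrum(
            rng.standard_normal(4096), rng.standard_normal(4096), _small_cfg()
        )
        assert np.allclose(np.diff(spec.freqs), FS / 1024)

    def test_scale_and_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8 * 1024)
        y = np.roll(x, 7) + 0.5 * rng.standard_normal(8 * 1024)
        a = coherence_spectrum(x, y, _small_cfg())
        b = coherence_spectrum(5.0 * x + 2.0, -0.3 * y + 11.0, _small_cfg())
        np.testing.assert_allclose(a.coh, b.coh, atol=1e-10)

    def test_delay_changes_phase_linearly_and_coherence_not_at_all(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(16 * 1024)
        d = 13
        # circular delay within each analysis window: an exact delay for the DFT
        y = np.roll(x.reshape(16, 1024), d, axis=1).ravel()
        spec0 = coherence_spectrum(x, x, _small_cfg())
        spec = coherence_spectrum(x, y, _small_cfg())
        np.testing.assert_allclose(spec.coh, spec0.coh, atol=1e-6)
        expected = -2 * np.pi * spec.freqs * d / FS
        dphi = np.angle(np.exp(1j * (spec.phase - expected)))
        assert np.max(np.abs(dphi)) < 1e-6

    def test_too_few_windows_raises(self):
        with pytest.raises(InsufficientDataError):
            coherence_spectrum(np.zeros(1500), np.zeros(1500), _small_cfg())


class TestSignificance:
    def test_closed_forms(self):
        assert coherence_significance(2, 0.05) == pytest.approx(0.95)
        assert coherence_significance(21, 0.05) == pytest.approx(0.1391, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(InsufficientDataError):
            coherence_significance(1, 0.05)

    @pytest.mark.parametrize("L", [5, 20, 100])
    def test_type_one_error_calibration(self, L):
        rng = np.random.default_rng(100 + L)
        x = rng.standard_normal(L * 4096)
        y = rng.standard_normal(L * 4096)
        spec = coherence_spectrum(x, y, _small_cfg(window_len=4096))
        frac = spec.significant.mean()
        se = math.sqrt(0.05 * 0.95 / len(spec.coh))
        assert abs(frac - 0.05) <= 3 * se


class TestAverageCoherence:
    def _noise_spec(self, seed, L=8):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(L * 1024)
        y = np.roll(x, 5) + rng.standard_normal(L * 1024)
        return coherence_spectrum(x, y, _small_cfg())

    def test_mean_of_identical_spectra_is_that_spectrum(self):
        s = self._noise_spec(0)
        avg = average_coherence([s, s, s])
        np.testing.assert_allclose(avg.coh, s.coh, atol=1e-12)

    def test_arithmetic_mean_of_two(self):
        a, b = self._noise_spec(1), self._noise_spec(2)
        avg = average_coherence([a, b])
        np.testing.assert_allclose(avg.coh, (a.coh + b.coh) / 2, atol=1e-12)
        assert avg.n_segments == a.n_segments + b.n_segments

    def test_variance_reduction_across_pairs(self):
        specs = [self._noise_spec(s) for s in range(12)]
        avg = average_coherence(specs)
        band = slice(10, 200)
        var_avg = np.var(avg.coh[band])
        assert all(var_avg < np.var(s.coh[band]) for s in specs)

    def test_mismatched_grids_raise(self):
        a = self._noise_spec(1)
        rng = np.random.default_rng(9)
        b = coherence_spectrum(
            rng.standard_normal(4096), rng.standard_normal(4096),
            _small_cfg(window_len=2048),
        )
        with pytest.raises(GridError):
            average_coherence([a, b])


class TestCircularMean:
    def test_identical_angles(self):
        assert circular_mean_phase([0.1, 0.1]) == pytest.approx(0.1)

    def test_resultant_of_quarter_turn(self):
        assert circular_mean_phase([0.0, math.pi / 2]) == pytest.approx(math.pi / 4)

    def test_wraparound_near_pi(self):
        got = circular_mean_phase([math.pi - 0.01, -math.pi + 0.01])
        assert got == pytest.approx(math.pi, abs=1e-9)

    def test_weighted(self):
        got = circular_mean_phase([0.0, 1.0], weights=[3.0, 0.0])
        assert got == pytest.approx(0.0)

    def test_undefined_mean_raises(self):
        with pytest.raises(UndefinedMeanError):
            circular_mean_phase([0.0, math.pi])

    @given(
        st.lists(st.floats(-3.0, 3.0), min_size=2, max_size=10),
        st.floats(-3.0, 3.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_rotation_equivariance(self, phases, c):
        try:
            base = circular_mean_phase(phases)
        except UndefinedMeanError:
            return
        rotated = circular_mean_phase(np.asarray(phases) + c)
        diff = np.angle(np.exp(1j * (rotated - base - c)))
        assert abs(diff) < 1e-9


class TestPooledBandPhase:
    def _spec(self, phase_value, coh_value, L=10):
        freqs = np.arange(1, 101, dtype=float)
        return CoherenceSpectrum(
            freqs=freqs,
            coh=np.full_like(freqs, coh_value),
            phase=np.full_like(freqs, phase_value),
            n_segments=L,
            sig_level=coherence_significance(L),
        )

    def test_identical_phases_recovered(self):
        mean, counts, edges = pooled_band_phase([self._spec(1.2, 0.8)] * 3, (8, 12))
        assert mean == pytest.approx(1.2)
        assert counts.sum() == 15  # 5 bins in [8,12] x 3 spectra

    def test_no_significant_bins_raises(self):
        with pytest.raises(UndefinedMeanError):
            pooled_band_phase([self._spec(1.0, 0.01)], (8, 12))


class TestPhaseSlopeDelay:
    def _constructed(self, delay_s, intercept=1.0):
        freqs = np.arange(1.0, 129.0)
        phase = intercept - 2 * np.pi * freqs * delay_s
        phase = np.angle(np.exp(1j * phase))
        return CoherenceSpectrum(
            freqs=freqs,
            coh=np.full_like(freqs, 0.9),
            phase=phase,
            n_segments=20,
            sig_level=coherence_significance(20),
        )

    def test_constructed_delay_recovered_exactly(self):
        est = phase_slope_delay(self._constructed(0.005), (20.0, 100.0))
        assert est.delay == pytest.approx(0.005, abs=1e-6)

    def test_constant_phase_gives_zero_delay(self):
        est = phase_slope_delay(self._constructed(0.0), (20.0, 100.0))
        assert est.delay == pytest.approx(0.0, abs=1e-9)
        assert est.ci95[0] <= 0.0 <= est.ci95[1]

    def test_too_few_significant_bins_raises(self):
        spec = self._constructed(0.003)
        spec = CoherenceSpectrum(
            freqs=spec.freqs, coh=np.full_like(spec.freqs, 0.01),
            phase=spec.phase, n_segments=20, sig_level=spec.sig_level,
        )
        with pytest.raises(InsufficientDataError):
            phase_slope_delay(spec, (20.0, 100.0))
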