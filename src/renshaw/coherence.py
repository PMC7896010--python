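"""Point-process / membrane-potential coherence and phase analysis.

The stimulus train is binarized at the trace sample rate (one in the bin
containing each stimulus onset, zero otherwise). Both signals are cut into
non-overlapping, non-tapered windows of 2**14 = 16,384 samples (1.53 Hz
resolution at 25 kHz); each window is demeaned and Fourier transformed, and
the magnitude-squared coherence and cross-spectral phase are formed over the
L windows. The analytic significance limit for a coherence estimate from L
segments at level alpha is ``1 - alpha ** (1 / (L - 1))``.

Phase convention: ``phase(f) = arg sum_i conj(X_i(f)) * Y_i(f)`` with x the
stimulus and y the membrane potential. Delaying y by d seconds changes the
phase by ``-2*pi*f*d`` at every frequency, so a positive transmission delay
produces a negative phase-frequency slope and the phase-slope delay estimate
is ``-slope / (2*pi)``. A negative-going (inhibitory) response contributes an
extra pi, which is why loop phases near 10 Hz fall in (0, pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from renshaw.errors import (
    ConfigurationError,
    GridError,
    InsufficientDataError,
    UndefinedMeanError,
)
from renshaw.synthetic import StimulusTrain

__all__ = [
    "CoherenceConfig",
    "CoherenceSpectrum",
    "DelayEstimate",
    "binarize_train",
    "coherence_spectrum",
    "coherence_significance",
    "average_coherence",
    "circular_mean_phase",
    "pooled_band_phase",
    "phase_slope_delay",
]


@dataclass(frozen=True)
class CoherenceConfig:
    window_len: int = 16384
    sample_rate: float = 25000.0
    alpha: float = 0.05
    demean: bool = True
    taper: str | None = None  # None = rectangular; "hann" optional

    def __post_init__(self) -> None:
        wl = self.window_len
        if wl < 256 or (wl & (wl - 1)) != 0:
            raise ConfigurationError("window_len must be a power of two >= 256")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.taper not in (None, "hann"):
            raise ConfigurationError("taper must be None or 'hann'")

    @property
    def resolution(self) -> float:
        return self.sample_rate / self.window_len


@dataclass(frozen=True)
class CoherenceSpectrum:
    freqs: np.ndarray        # Hz, spacing sample_rate / window_len (DC excluded)
    coh: np.ndarray          # magnitude-squared coherence in [0, 1]
    phase: np.ndarray        # radians in (-pi, pi]
    n_segments: int
    sig_level: float
    config: CoherenceConfig = field(default_factory=CoherenceConfig)

    @property
    def significant(self) -> np.ndarray:
        return self.coh > self.sig_level

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])


@dataclass(frozen=True)
class DelayEstimate:
    delay: float                 # seconds
    ci95: tuple[float, float]    # seconds
    fit_range: tuple[float, float]
    slope: float                 # radians per Hz
    n_bins: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.delay <= hi:
            raise ValueError("delay must lie inside its confidence interval")


def binarize_train(
    train: StimulusTrain | np.ndarray,
    sample_rate: float,
    n_samples: int,
) -> np.ndarray:
    """0/1 waveform with a one in the bin containing each stimulus onset."""
    times = train.times if isinstance(train, StimulusTrain) else np.asarray(train, float)
    sig = np.zeros(n_samples, dtype=float)
    if times.size == 0:
        return sig
    idx = np.floor(times * sample_rate).astype(int)
    bad = idx >= n_samples
    if bad.any():
        raise ValueError(
            f"event(s) beyond trace end: t={times[bad][:3].tolist()} "
            f"(trace covers {n_samples / sample_rate:.6g} s)"
        )
    sig[idx] = 1.0
    return sig


def coherence_significance(L: int, alpha: float = 0.05) -> float:
    """Coherence value exceeded with probability ``alpha`` under independence."""
    if L < 2:
        raise InsufficientDataError("significance limit requires L >= 2 segments")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return 1.0 - alpha ** (1.0 / (L - 1))


def _segment_ffts(x: np.ndarray, config: CoherenceConfig) -> np.ndarray:
    wl = config.window_len
    L = len(x) // wl
    segs = np.asarray(x[: L * wl], dtype=float).reshape(L, wl)
    if config.demean:
        segs = segs - segs.mean(axis=1, keepdims=True)
    if config.taper == "hann":
        segs = segs * np.hanning(wl)[None, :]
    return np.fft.rfft(segs, axis=1)


def coherence_spectrum(
    x: np.ndarray, y: np.ndarray, config: CoherenceConfig | None = None
) -> CoherenceSpectrum:
    """Magnitude-squared coherence and phase between sampled signals x and y.

    Uses L non-overlapping windows (trailing partial window discarded), each
    demeaned (unless disabled) and untapered by default.
    """
    config = config or CoherenceConfig()
    if len(x) != len(y):
        raise ConfigurationError("signals must have equal length")
    L = len(x) // config.window_len
    if L < 2:
        raise InsufficientDataError(
            f"need >= 2 complete windows of {config.window_len} samples, got {L}"
        )
    X = _segment_ffts(x, config)
    Y = _segment_ffts(y, config)
    cross = np.sum(np.conj(X) * Y, axis=0)
    pxx = np.sum(np.abs(X) ** 2, axis=0)
    pyy = np.sum(np.abs(Y) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(cross) ** 2 / (pxx * pyy)
    coh = np.nan_to_num(coh, nan=0.0)
    phase = np.angle(cross)
    freqs = np.fft.rfftfreq(config.window_len, 1.0 / config.sample_rate)
    return CoherenceSpectrum(
        freqs=freqs[1:],
        coh=np.clip(coh[1:], 0.0, 1.0),
        phase=phase[1:],
        n_segments=L,
        sig_level=coherence_significance(L, config.alpha),
        config=config,
    )


def average_coherence(spectra: Sequence[CoherenceSpectrum]) -> CoherenceSpectrum:
    """Average coherence across recording pairs on a shared frequency grid.

    Coherence is the per-frequency arithmetic mean. The phase of the averaged
    spectrum is, per bin, the circular mean over the spectra whose own
    coherence exceeds their own significance limit (NaN where none does).
    The significance limit of the average is recomputed with L equal to the
    total segment count, the natural pooled extension of the single-spectrum
    formula.
    """
    if not spectra:
        raise InsufficientDataError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
            raise GridError("spectra have mismatched frequency grids")
    coh = np.mean([s.coh for s in spectra], axis=0)
    L_total = int(sum(s.n_segments for s in spectra))
    phase = np.full_like(ref.phase, np.nan)
    for i in range(len(ref.freqs)):
        contrib = [s.phase[i] for s in spectra if s.coh[i] > s.sig_level]
        if contrib:
            phase[i] = circular_mean_phase(np.asarray(contrib))
    return CoherenceSpectrum(
        freqs=ref.freqs.copy(),
        coh=coh,
        phase=phase,
        n_segments=L_total,
        sig_level=coherence_significance(L_total, ref.config.alpha),
        config=ref.config,
    )


def circular_mean_phase(
    phases: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> float:
    """Circular mean: argument of the weighted resultant, in (-pi, pi]."""
    ph = np.asarray(phases, dtype=float)
    if ph.size == 0:
        raise UndefinedMeanError("no phases to average")
    if weights is None:
        w = np.ones_like(ph)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ConfigurationError("weights must be non-negative")
        if not np.any(w > 0):
            raise UndefinedMeanError("all weights are zero")
    resultant = np.sum(w * np.exp(1j * ph))
    if np.abs(resultant) / np.sum(w) < 1e-9:
        raise UndefinedMeanError("resultant length is (near) zero; mean undefined")
    ang = float(np.angle(resultant))
    if ang <= -math.pi:  # normalize the branch cut to (-pi, pi]
        ang += 2 * math.pi
    return ang


def pooled_band_phase(
    spectra: Sequence[CoherenceSpectrum],
    band: tuple[float, float],
    n_hist_bins: int = 24,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pool significant phases from all (spectrum, bin) pairs inside ``band``.

    Every bin with coherence above its spectrum's significance limit
    contributes one phase. Returns ``(circular mean, histogram counts,
    histogram bin edges)`` — the counts are what a circular rose plot shows.
    """
    pooled: list[float] = []
    for s in spectra:
        mask = s.band_mask(band) & s.significant
        pooled.extend(np.asarray(s.phase)[mask].tolist())
    if not pooled:
        raise UndefinedMeanError("no significant bins in the requested band")
    phases = np.asarray(pooled)
    edges = np.linspace(-math.pi, math.pi, n_hist_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return circular_mean_phase(phases), counts, edges


def phase_slope_delay(
    spectrum: CoherenceSpectrum,
    fit_range: tuple[float, float] = (20.0, 100.0),
    alpha: float = 0.05,
) -> DelayEstimate:
    """Delay implied by the slope of the phase-frequency relationship.

    The phase is unwrapped across all bins in ``fit_range`` and an ordinary
    least-squares line is fitted to the bins whose coherence exceeds the
    significance limit; the delay is ``-slope / (2*pi)`` with a t-based
    confidence interval on the slope.
    """
    in_range = spectrum.band_mask(fit_range)
    if in_range.sum() < 3:
        raise InsufficientDataError("fit range covers fewer than 3 bins")
    f = spectrum.freqs[in_range]
    ph = np.unwrap(spectrum.phase[in_range])
    use = spectrum.significant[in_range]
    if use.sum() < 3:
        raise InsufficientDataError("fewer than 3 significant bins in fit range")
    f, ph = f[use], ph[use]
    res = stats.linregress(f, ph)
    n = len(f)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    delay = -res.slope / (2.0 * math.pi)
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    half = tcrit * stderr / (2.0 * math.pi)
    lo, hi = sorted((delay - half, delay + half))
    return DelayEstimate(
        delay=float(delay),
        ci95=(float(lo), float(hi)),
        fit_range=fit_range,
        slope=float(res.slope),
        n_bins=n,
    )
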