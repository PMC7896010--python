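"""Synthetic stimulus trains and intracellular recordings with known ground truth.

This module emulates the raw material of an intracellular study of recurrent
inhibition: motor nerves stimulated as independent Poisson processes (10 Hz
mean rate, 3 ms refractory dead time) while the motoneuron membrane potential
is sampled at 25 kSamples/s. A synthetic recording contains, per stimulus, a
brief stimulus artifact, a small antidromic field potential, and a
negative-going recurrent IPSP drawn from a configurable kernel; optionally an
antidromic spike with an after-hyperpolarization (AHP), plus membrane noise.

Nonlinear IPSP summation is emulated phenomenologically: each IPSP's
amplitude is scaled by a factor that depends on the interval since the most
recent preceding stimulus of the same nerve, combining short-interval
paired-pulse depression (exponential recovery) with a low-rate suppression
band (Gaussian bump around ~6 Hz intervals). The generating parameters are
retained in the returned :class:`Recording` so downstream estimators can be
tested against ground truth.

Units: traces are stored in millivolts; IPSP, artifact, field and noise
amplitudes are configured in microvolts (1 mV = 1000 µV). IPSP amplitudes are
given as positive numbers; the deflection itself is negative-going.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from renshaw._rng import child_rng
from renshaw.errors import ConfigurationError

__all__ = [
    "TrainConfig",
    "StimulusTrain",
    "IPSPKernel",
    "NonlinearityConfig",
    "AntidromicConfig",
    "RecordingConfig",
    "Recording",
    "generate_poisson_train",
    "synthesize_recording",
    "ipsp_scale_factor",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Parameters of a Poisson stimulus train with refractory dead time.

    ``mean_rate`` is the long-run event rate actually achieved: intervals are
    drawn as ``dead_time`` plus an exponential with mean
    ``1/mean_rate - dead_time``, so the dead time does not bias the rate.
    """

    duration: float
    mean_rate: float = 10.0
    dead_time: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ConfigurationError("mean_rate must be > 0")
        if self.dead_time < 0:
            raise ConfigurationError("dead_time must be >= 0")
        if self.mean_rate * self.dead_time >= 1:
            raise ConfigurationError(
                "mean_rate * dead_time must be < 1 so the target rate is achievable"
            )
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")


@dataclass(frozen=True)
class StimulusTrain:
    """Ordered stimulus times (seconds) for one nerve."""

    nerve_id: str
    times: np.ndarray
    config: TrainConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("stimulus times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class IPSPKernel:
    """Difference-of-exponentials IPSP waveform (negative-going).

    ``amplitude_uv`` is the peak onset-to-peak deflection in microvolts; the
    waveform is normalized so its most negative point equals ``-amplitude_uv``.
    """

    latency: float = 0.0025
    amplitude_uv: float = 200.0
    rise_tau: float = 0.0015
    decay_tau: float = 0.008

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ConfigurationError("latency must be >= 0")
        if self.amplitude_uv < 0:
            raise ConfigurationError("amplitude_uv must be >= 0")
        if not (0 < self.rise_tau < self.decay_tau):
            raise ConfigurationError("need 0 < rise_tau < decay_tau")

    @property
    def peak_time(self) -> float:
        """Time of the negative peak, measured from stimulus onset."""
        r, d = self.rise_tau, self.decay_tau
        return self.latency + r * d / (d - r) * math.log(d / r)

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the kernel (millivolts) at times ``t`` after stimulus onset."""
        t = np.asarray(t, dtype=float)
        s = t - self.latency
        r, d = self.rise_tau, self.decay_tau
        tpk = r * d / (d - r) * math.log(d / r)
        norm = math.exp(-tpk / d) - math.exp(-tpk / r)
        out = np.zeros_like(s)
        pos = s > 0
        out[pos] = np.exp(-s[pos] / d) - np.exp(-s[pos] / r)
        return -(self.amplitude_uv / 1000.0) * out / norm

    def sample(self, sample_rate: float, tail: float = 22.0) -> np.ndarray:
        """Sampled template starting at stimulus onset (lag 0)."""
        t_end = self.latency + tail * self.decay_tau
        n = int(round(t_end * sample_rate)) + 1
        return self.waveform(np.arange(n) / sample_rate)


@dataclass(frozen=True)
class NonlinearityConfig:
    """Phenomenological IPSP amplitude nonlinearity.

    The scale factor applied to an IPSP at interval ``d`` since the most
    recent prior stimulus of the same nerve is::

        (1 - short_depression_max * exp(-d / short_recovery_tau))
        * (1 - low_rate_depression_max
               * exp(-(d - low_rate_center)**2 / (2 * low_rate_width**2)))

    Defaults emulate the two experimentally observed phenomena: paired-pulse
    depression recovering over tens of milliseconds, and suppression of IPSPs
    recurring at 5-7 Hz (intervals around ~170 ms).
    """

    short_depression_max: float = 0.6
    short_recovery_tau: float = 0.008
    low_rate_depression_max: float = 0.25
    low_rate_center: float = 1.0 / 6.0
    low_rate_width: float = 0.045

    def __post_init__(self) -> None:
        for name in ("short_depression_max", "low_rate_depression_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("short_recovery_tau", "low_rate_center", "low_rate_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @classmethod
    def linear(cls) -> "NonlinearityConfig":
        """A configuration with both depression terms switched off."""
        return cls(short_depression_max=0.0, low_rate_depression_max=0.0)

    @property
    def is_linear(self) -> bool:
        return self.short_depression_max == 0 and self.low_rate_depression_max == 0


@dataclass(frozen=True)
class AntidromicConfig:
    """Antidromic spike + AHP added to the intracellular trace for one nerve."""

    nerve_id: str
    spike_latency: float = 0.0008
    spike_amplitude_mv: float = 60.0
    spike_width: float = 0.0004
    ahp_depth_mv: float = 2.0
    ahp_tau: float = 0.015

    def sample(self, sample_rate: float) -> np.ndarray:
        t_end = self.spike_latency + 8.0 * self.ahp_tau
        t = np.arange(int(round(t_end * sample_rate)) + 1) / sample_rate
        s = t - self.spike_latency
        spike = self.spike_amplitude_mv * np.exp(-0.5 * (s / (self.spike_width / 2.355)) ** 2)
        ahp = np.zeros_like(s)
        pos = s > self.spike_width
        u = s[pos] - self.spike_width
        ahp[pos] = -self.ahp_depth_mv * (u / self.ahp_tau) * np.exp(1 - u / self.ahp_tau)
        return spike + ahp


@dataclass(frozen=True)
class RecordingConfig:
    """Full parameterization of a synthetic recording."""

    kernels: Mapping[str, IPSPKernel] = field(default_factory=dict)
    sample_rate: float = 25000.0
    resting_mv: float = -70.0
    noise_sd_uv: float = 100.0
    noise_cutoff_hz: float | None = None
    artifact_amplitude_uv: float = 2000.0
    artifact_duration: float = 0.001
    field_amplitude_uv: float = 100.0
    field_latency: float = 0.0004
    field_duration: float = 0.001
    antidromic: AntidromicConfig | None = None
    nonlinearity: NonlinearityConfig = field(default_factory=NonlinearityConfig)
    motoneuron_id: str = "mn0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        for name in ("artifact_duration", "field_duration", "field_latency"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.noise_sd_uv < 0:
            raise ConfigurationError("noise_sd_uv must be >= 0")


@dataclass(frozen=True)
class Recording:
    """Synthetic (or simulated) recording plus its generating ground truth."""

    intracellular: np.ndarray
    extracellular: np.ndarray
    sample_rate: float
    trains: tuple[StimulusTrain, ...]
    truth: RecordingConfig
    meta: dict

    def __post_init__(self) -> None:
        if len(self.intracellular) != len(self.extracellular):
            raise ConfigurationError("intra/extracellular traces must share length")

    @property
    def duration(self) -> float:
        return len(self.intracellular) / self.sample_rate

    def train(self, nerve_id: str) -> StimulusTrain:
        for tr in self.trains:
            if tr.nerve_id == nerve_id:
                return tr
        raise KeyError(f"no stimulus train for nerve {nerve_id!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_poisson_train(config: TrainConfig, nerve_id: str = "nerve") -> StimulusTrain:
    """Draw a Poisson stimulus train with refractory dead time.

    Inter-event intervals are ``dead_time + Exponential(1/mean_rate - dead_time)``
    so that the long-run achieved rate equals ``mean_rate`` exactly.
    """
    rng = child_rng(config.seed, "train", nerve_id)
    if config.duration == 0:
        return StimulusTrain(nerve_id, np.empty(0), config)
    exp_mean = 1.0 / config.mean_rate - config.dead_time
    times: list[np.ndarray] = []
    t_last = 0.0
    # draw in blocks until past the end; first event also respects the interval law
    expected = int(config.duration * config.mean_rate * 1.2) + 64
    while t_last < config.duration:
        gaps = config.dead_time + rng.exponential(exp_mean, size=expected)
        block = t_last + np.cumsum(gaps)
        times.append(block)
        t_last = block[-1]
    all_times = np.concatenate(times)
    return StimulusTrain(nerve_id, all_times[all_times < config.duration], config)


def ipsp_scale_factor(
    stim_times_before: Sequence[float] | np.ndarray,
    t: float,
    nl: NonlinearityConfig,
) -> float:
    """Amplitude scale factor for an IPSP at time ``t`` given prior stimuli.

    Depends only on the most recent prior stimulus; returns 1.0 for an empty
    history (full recovery).
    """
    prior = np.asarray(stim_times_before, dtype=float)
    if prior.size == 0:
        return 1.0
    if np.any(prior >= t):
        raise ValueError("stim_times_before must all precede t")
    d = t - prior.max()
    short = 1.0 - nl.short_depression_max * math.exp(-d / nl.short_recovery_tau)
    low = 1.0 - nl.low_rate_depression_max * math.exp(
        -((d - nl.low_rate_center) ** 2) / (2.0 * nl.low_rate_width**2)
    )
    return float(min(1.0, max(0.0, short * low)))


def _add_at(trace: np.ndarray, start: int, template: np.ndarray) -> None:
    n = len(trace)
    if start >= n:
        return
    stop = min(n, start + len(template))
    trace[start:stop] += template[: stop - start]


def _membrane_noise(
    rng: np.random.Generator, n: int, sd_mv: float, cutoff_hz: float | None, fs: float
) -> np.ndarray:
    noise = rng.standard_normal(n)
    if cutoff_hz is not None:
        # one-pole low-pass, renormalized to the requested standard deviation
        a = math.exp(-2.0 * math.pi * cutoff_hz / fs)
        from scipy.signal import lfilter

        noise = lfilter([1.0 - a], [1.0, -a], noise)
        gain = math.sqrt((1.0 - a) ** 2 / (1.0 - a**2))
        noise /= gain
    return sd_mv * noise


def _artifact_template(cfg: RecordingConfig) -> np.ndarray:
    n = int(round(cfg.artifact_duration * cfg.sample_rate))
    if n == 0 or cfg.artifact_amplitude_uv == 0:
        return np.empty(0)
    t = np.arange(n) / n
    return (cfg.artifact_amplitude_uv / 1000.0) * np.sin(2.0 * np.pi * t)


def _field_template(cfg: RecordingConfig) -> np.ndarray:
    n_total = int(round((cfg.field_latency + cfg.field_duration) * cfg.sample_rate))
    n_lat = int(round(cfg.field_latency * cfg.sample_rate))
    if n_total - n_lat <= 0 or cfg.field_amplitude_uv == 0:
        return np.empty(0)
    tpl = np.zeros(n_total)
    u = np.arange(n_total - n_lat) / (n_total - n_lat)
    tpl[n_lat:] = -(cfg.field_amplitude_uv / 1000.0) * np.sin(np.pi * u) ** 2
    return tpl


def synthesize_recording(
    config: RecordingConfig, trains: Sequence[StimulusTrain]
) -> Recording:
    """Build a synthetic intracellular + extracellular recording.

    The intracellular trace is the resting level plus, for every stimulus, a
    stimulus artifact, an antidromic field potential, and (for nerves with a
    configured kernel) an IPSP whose amplitude is scaled by
    :func:`ipsp_scale_factor`. The extracellular trace contains artifact and
    field with independent noise but no IPSP. Ground truth is retained.
    """
    ids = [tr.nerve_id for tr in trains]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("trains must have distinct nerve_ids")
    unknown = set(config.kernels) - set(ids)
    if unknown:
        raise ConfigurationError(f"kernels reference unknown nerves: {sorted(unknown)}")

    fs = config.sample_rate
    duration = max((tr.config.duration for tr in trains), default=0.0)
    n = int(round(duration * fs))
    intra = np.full(n, config.resting_mv, dtype=float)
    extra = np.zeros(n, dtype=float)

    art = _artifact_template(config)
    fld = _field_template(config)
    anti_tpl = config.antidromic.sample(fs) if config.antidromic is not None else None

    for tr in trains:
        if tr.times.size and tr.times.max() >= duration:
            raise ConfigurationError("stimulus times exceed the trace duration")
        kern = config.kernels.get(tr.nerve_id)
        ktpl = kern.sample(fs) if kern is not None else None
        idx = np.round(tr.times * fs).astype(int)
        for k, i0 in enumerate(idx):
            if art.size:
                _add_at(intra, i0, art)
                _add_at(extra, i0, art)
            if fld.size:
                _add_at(intra, i0, fld)
                _add_at(extra, i0, fld)
            if ktpl is not None:
                if k == 0 or config.nonlinearity.is_linear:
                    factor = 1.0
                else:
                    factor = ipsp_scale_factor(
                        tr.times[k - 1 : k], tr.times[k], config.nonlinearity
                    )
                _add_at(intra, i0, factor * ktpl)
            if anti_tpl is not None and config.antidromic.nerve_id == tr.nerve_id:
                _add_at(intra, i0, anti_tpl)

    if config.noise_sd_uv > 0:
        sd_mv = config.noise_sd_uv / 1000.0
        intra += _membrane_noise(
            child_rng(config.seed, "noise", "intracellular"), n, sd_mv,
            config.noise_cutoff_hz, fs,
        )
        extra += _membrane_noise(
            child_rng(config.seed, "noise", "extracellular"), n, sd_mv,
            config.noise_cutoff_hz, fs,
        )

    anti_nerves = [config.antidromic.nerve_id] if config.antidromic is not None else []
    meta = {"motoneuron_id": config.motoneuron_id, "antidromic_nerves": anti_nerves}
    return Recording(intra, extra, fs, tuple(trains), config, meta)
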