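"""Conductance-based recurrent-inhibition feedback-loop simulation.

One recorded motoneuron (passive two-compartment, soma + dendrite) receives
glycinergic input from its pool of Renshaw cells (exponential
integrate-and-fire with a 1 ms absolute refractory period). Each motor-nerve
stimulus antidromically activates, after an axonal conduction delay, all
motor axons converging on every Renshaw cell simultaneously, delivering a
synchronized compound EPSP conductance (alpha function; the configurable
"rise time" is its time to peak). Renshaw spikes reach the motoneuron
dendrite after a synaptic delay as glycinergic alpha conductances with a
reversal potential of -80 mV.

Because the protocol drives the motor axons directly with the nerve stimulus
and the recorded motoneuron is held at rest, the other motoneurons of the
pool cannot influence the recorded cell; the pool sizes (``n_motoneurons``,
``n_mn_per_rc``) therefore enter only through the size of the compound
axonal volley, which is an exact reduction of the full pool under this
protocol.

The compound EPSP conductance amplitude is charge-normalized across rise
times: the peak scales as 1/rise so that 1, 4 and 8 ms EPSPs deliver the
same conductance charge per volley, isolating the effect of EPSP duration.

The somatic potential is integrated at dt = 20 µs and decimated to 25 kHz;
the first second is discarded while conductances reach steady state. The
output is analyzed with the identical coherence code path used for
experimental recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from renshaw._loop_kernel import run_loop
from renshaw._rng import child_rng
from renshaw.coherence import (
    CoherenceConfig,
    CoherenceSpectrum,
    binarize_train,
    circular_mean_phase,
    coherence_spectrum,
)
from renshaw.errors import ConfigurationError, StabilityError
from renshaw.synthetic import StimulusTrain, TrainConfig, _membrane_noise

__all__ = [
    "MotoneuronParams",
    "RenshawParams",
    "GlycineParams",
    "ModelConfig",
    "SimulationResult",
    "simulate_loop",
    "model_coherence",
    "band_phase",
    "volley_response",
]


@dataclass(frozen=True)
class MotoneuronParams:
    """Passive two-compartment recorded motoneuron.

    Defaults give a somatic input resistance of ~2.6 MOhm, a membrane time
    constant of 6 ms, and a dendrite-to-soma steady-state attenuation of 0.9
    through the coupling conductance.
    """

    c_soma_pf: float = 1800.0
    g_leak_soma_ns: float = 300.0
    c_dend_pf: float = 2400.0
    g_leak_dend_ns: float = 400.0
    g_couple_ns: float = 2700.0
    e_leak_mv: float = -70.0


@dataclass(frozen=True)
class RenshawParams:
    """Exponential integrate-and-fire Renshaw cell (tau_m = 8 ms)."""

    c_pf: float = 100.0
    g_leak_ns: float = 12.5
    e_leak_mv: float = -65.0
    v_thresh_mv: float = -50.0
    delta_t_mv: float = 2.0
    v_cut_mv: float = -30.0
    v_reset_mv: float = -65.0
    refractory_ms: float = 1.0
    e_exc_mv: float = 0.0
    thresh_jitter_mv: float = 1.0


@dataclass(frozen=True)
class GlycineParams:
    """Glycinergic Renshaw-to-motoneuron synapse on the dendrite."""

    e_rev_mv: float = -80.0
    tau_ms: float = 3.0
    unitary_peak_ns: float = 1.2


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of the feedback-loop simulation."""

    epsp_rise_ms: float = 1.0
    duration_s: float = 1001.0
    discard_s: float = 1.0
    dt: float = 2.0e-5
    output_rate: float = 25000.0
    n_motoneurons: int = 177
    n_rc_per_mn: int = 20
    n_mn_per_rc: int = 50
    axon_delay_ms: float = 1.5
    synapse_delay_ms: float = 1.0
    epsp_unitary_gpeak_ns: float = 2.0   # unitary axonal EPSP peak at 1 ms rise
    mn_params: MotoneuronParams = field(default_factory=MotoneuronParams)
    rc_params: RenshawParams = field(default_factory=RenshawParams)
    glycine_params: GlycineParams = field(default_factory=GlycineParams)
    mn_noise_sd_uv: float = 50.0
    mn_noise_cutoff_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= self.discard_s:
            raise ConfigurationError("duration_s must exceed discard_s")
        if self.dt > 1.0 / self.output_rate + 1e-15:
            raise ConfigurationError("dt must be <= 1 / output_rate")
        for name in ("n_motoneurons", "n_rc_per_mn", "n_mn_per_rc"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.epsp_rise_ms <= 0:
            raise ConfigurationError("epsp_rise_ms must be > 0")
        decim = 1.0 / (self.output_rate * self.dt)
        if abs(decim - round(decim)) > 1e-9:
            raise ConfigurationError("1/(output_rate*dt) must be an integer")

    @property
    def compound_epsp_gpeak_ns(self) -> float:
        """Per-volley compound conductance peak, charge-normalized by rise time."""
        return self.n_mn_per_rc * self.epsp_unitary_gpeak_ns / self.epsp_rise_ms


@dataclass(frozen=True)
class SimulationResult:
    vm: np.ndarray                       # somatic mV at output_rate, post-discard
    train: StimulusTrain
    spikes_rc: tuple[np.ndarray, ...]    # spike times (s) per Renshaw cell
    config: ModelConfig

    @property
    def duration(self) -> float:
        return len(self.vm) / self.config.output_rate


def simulate_loop(config: ModelConfig, train: StimulusTrain) -> SimulationResult:
    """Run the loop simulation for the given stimulus train.

    Fully reproducible given ``config.seed`` (Renshaw threshold jitter and
    the additive somatic membrane noise are the only random elements).
    """
    dt_ms = config.dt * 1e3
    n_steps = int(round(config.duration_s / config.dt))
    decim = int(round(1.0 / (config.output_rate * config.dt)))
    discard_steps = int(round(config.discard_s / config.dt))
    n_out = int(round((config.duration_s - config.discard_s) * config.output_rate))

    times = train.times
    if times.size and times.max() >= config.duration_s:
        raise ConfigurationError("stimulus times exceed the simulation duration")
    stim_steps = np.round(
        (times + config.axon_delay_ms * 1e-3) / config.dt
    ).astype(np.int64)
    stim_steps = np.sort(stim_steps[stim_steps < n_steps])

    rc = config.rc_params
    rng = child_rng(config.seed, "loop", "rc_thresholds")
    vt = rc.v_thresh_mv + rc.thresh_jitter_mv * rng.standard_normal(config.n_rc_per_mn)

    vm = np.zeros(n_out)
    gly_sched = np.zeros(n_steps)
    cap = int(config.n_rc_per_mn * (len(stim_steps) + 16) * 16)
    spike_cells = np.zeros(cap, dtype=np.int64)
    spike_steps = np.zeros(cap, dtype=np.int64)

    mn = config.mn_params
    gly = config.glycine_params
    nsp = run_loop(
        n_steps,
        dt_ms,
        stim_steps,
        config.epsp_rise_ms,
        config.compound_epsp_gpeak_ns,
        rc.c_pf,
        rc.g_leak_ns,
        rc.e_leak_mv,
        vt,
        rc.delta_t_mv,
        rc.v_cut_mv,
        rc.v_reset_mv,
        int(round(rc.refractory_ms / dt_ms)),
        rc.e_exc_mv,
        gly.tau_ms,
        gly.unitary_peak_ns,
        int(round(config.synapse_delay_ms / dt_ms)),
        gly.e_rev_mv,
        mn.c_soma_pf,
        mn.g_leak_soma_ns,
        mn.c_dend_pf,
        mn.g_leak_dend_ns,
        mn.g_couple_ns,
        mn.e_leak_mv,
        discard_steps,
        decim,
        vm,
        gly_sched,
        spike_cells,
        spike_steps,
    )
    if nsp < 0:
        raise StabilityError(
            "membrane potential diverged beyond +/-200 mV; use a smaller dt"
        )
    if config.mn_noise_sd_uv > 0:
        vm = vm + _membrane_noise(
            child_rng(config.seed, "loop", "mn_noise"),
            n_out,
            config.mn_noise_sd_uv / 1000.0,
            config.mn_noise_cutoff_hz,
            config.output_rate,
        )
    spike_t = spike_steps[:nsp] * config.dt
    cells = spike_cells[:nsp]
    spikes = tuple(
        np.sort(spike_t[cells == j]) for j in range(config.n_rc_per_mn)
    )
    return SimulationResult(vm=vm, train=train, spikes_rc=spikes, config=config)


def model_coherence(
    result: SimulationResult, config: CoherenceConfig | None = None
) -> CoherenceSpectrum:
    """Coherence between the stimulus train and the simulated potential.

    Identical code path as for experimental recordings: the train is
    binarized at the output rate (re-referenced to the end of the discarded
    transient) and passed through :func:`renshaw.coherence.coherence_spectrum`.
    """
    config = config or CoherenceConfig(sample_rate=result.config.output_rate)
    t0 = result.config.discard_s
    times = result.train.times
    times = times[times >= t0] - t0
    x = binarize_train(times, config.sample_rate, len(result.vm))
    return coherence_spectrum(x, result.vm, config)


def band_phase(
    spectrum: CoherenceSpectrum,
    band: tuple[float, float] = (8.0, 12.0),
    significant_only: bool = False,
) -> float:
    """Circular-mean coherence phase over all bins in ``band``."""
    mask = spectrum.band_mask(band)
    if significant_only:
        mask &= spectrum.significant
    return circular_mean_phase(spectrum.phase[mask], weights=None)


def volley_response(
    config: ModelConfig, settle_s: float = 0.2, window_s: float = 0.3
) -> dict:
    """Diagnostics for a single stimulus volley (calibration aid).

    Runs a short noise-free simulation with one stimulus and reports the
    number of Renshaw spikes per cell, the compound somatic IPSP amplitude
    (µV), and the IPSP onset latency relative to the stimulus (ms).
    """
    cfg = replace(
        config,
        duration_s=settle_s + window_s,
        discard_s=0.0,
        mn_noise_sd_uv=0.0,
    )
    train = StimulusTrain("calib", np.array([settle_s]), TrainConfig(duration=cfg.duration_s))
    res = simulate_loop(cfg, train)
    fs = cfg.output_rate
    i0 = int(round(settle_s * fs))
    rest = res.vm[i0 - int(0.05 * fs) : i0].mean()
    seg = res.vm[i0 : i0 + int(window_s * fs)]
    ipsp_uv = float((rest - seg.min()) * 1e3)
    # onset: first sample deviating below rest by 5% of the IPSP depth
    depth = rest - seg.min()
    onset_idx = np.flatnonzero(seg < rest - 0.05 * depth)
    onset_ms = float(onset_idx[0] / fs * 1e3) if onset_idx.size else float("nan")
    spikes_per_cell = [
        int(np.sum((s >= settle_s) & (s < settle_s + 0.05))) for s in res.spikes_rc
    ]
    return {
        "spikes_per_cell": spikes_per_cell,
        "mean_spikes_per_cell": float(np.mean(spikes_per_cell)),
        "ipsp_amplitude_uv": ipsp_uv,
        "ipsp_onset_ms": onset_ms,
    }
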