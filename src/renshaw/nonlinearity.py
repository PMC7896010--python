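"""Conditional averaging: nonlinear IPSP summation versus interstimulus interval.

From the Poisson train, triggering stimuli T are selected that were preceded
by a conditioning stimulus C within a stated window. The average of the
membrane potential over the selected triggers contains the responses to both
C and T; the expected response to C — the all-stimulus average, time shifted
by each trigger's conditioning lag — is subtracted, leaving the conditioned
response to T alone. Its amplitude, expressed as a percentage of the
unconditioned (all-stimulus) IPSP, traces out a conditioning curve as the
window is stepped over short (0-50 ms) or long (up to 1 s, plotted as
frequency = 1/interval) intervals.

By default triggers with any additional stimulus between C and T are
excluded, so each conditioned average reflects a clean two-pulse interaction;
set ``exclude_intervening=False`` to keep them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from renshaw.coherence import CoherenceConfig, CoherenceSpectrum, binarize_train, coherence_spectrum
from renshaw.errors import ConfigurationError, InsufficientDataError, SupportError
from renshaw.popstats import benjamini_hochberg
from renshaw.signal_prep import TriggeredAverage, measure_ipsp, triggered_average
from renshaw.synthetic import Recording, StimulusTrain

__all__ = [
    "ConditioningWindow",
    "CurvePoint",
    "ConditioningCurve",
    "short_range_windows",
    "long_range_windows",
    "select_conditioned_triggers",
    "conditional_average_corrected",
    "conditioning_curve",
    "curve_significance",
    "linear_prediction_coherence",
]


@dataclass(frozen=True)
class ConditioningWindow:
    """Interval window [offset, offset + width) before the triggering stimulus."""

    offset: float
    width: float

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ConfigurationError("offset must be >= 0")
        if self.width <= 0:
            raise ConfigurationError("width must be > 0")

    @property
    def center(self) -> float:
        return self.offset + self.width / 2.0


@dataclass(frozen=True)
class CurvePoint:
    window: ConditioningWindow
    axis_value: float        # interval (s) or frequency (Hz) at the window center
    amplitude_pct: float     # percent of the unconditioned IPSP (NaN if too few triggers)
    n_triggers: int
    mean_lag: float          # mean conditioning lag of the selected triggers (s)
    sem: float = float("nan")


@dataclass(frozen=True)
class ConditioningCurve:
    nerve: str
    axis_mode: str           # "interval" | "frequency"
    points: tuple[CurvePoint, ...]
    unconditioned_uv: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_offset_ms": [p.window.offset * 1e3 for p in self.points],
                "window_width_ms": [p.window.width * 1e3 for p in self.points],
                "axis_value": [p.axis_value for p in self.points],
                "amplitude_pct": [p.amplitude_pct for p in self.points],
                "n": [p.n_triggers for p in self.points],
                "mean_lag_ms": [p.mean_lag * 1e3 for p in self.points],
                "sem": [p.sem for p in self.points],
            }
        )


def short_range_windows(
    width: float = 0.005, max_offset: float = 0.045, step: float = 0.005
) -> list[ConditioningWindow]:
    """Default short-interval grid: 5 ms windows, offsets 0-45 ms."""
    offsets = np.arange(0.0, max_offset + step / 2, step)
    return [ConditioningWindow(float(o), width) for o in offsets]


def long_range_windows(
    width: float = 0.100,
    min_center: float = 0.053,
    max_center: float = 1.000,
    n: int = 10,
) -> list[ConditioningWindow]:
    """Long-interval grid: 100 ms windows with centers 53-1000 ms (geometric)."""
    centers = np.geomspace(min_center, max_center, n)
    return [ConditioningWindow(float(c - width / 2.0), width) for c in centers]


def select_conditioned_triggers(
    train: StimulusTrain,
    window: ConditioningWindow,
    exclude_intervening: bool = True,
) -> list[tuple[float, float]]:
    """Triggers preceded by a conditioning stimulus inside ``window``.

    Returns ``(trigger time, conditioning lag)`` pairs; the lag refers to the
    most recent qualifying conditioner. With ``exclude_intervening`` (default)
    triggers with any other stimulus between conditioner and trigger are
    dropped.
    """
    times = train.times
    out: list[tuple[float, float]] = []
    lo, hi = window.offset, window.offset + window.width
    for i in range(1, len(times)):
        T = times[i]
        # most recent C with T - C in [lo, hi)  <=>  C in (T - hi, T - lo]
        j = int(np.searchsorted(times, T - lo, side="right")) - 1
        j = min(j, i - 1)
        if j < 0:
            continue
        C = times[j]
        if not (T - hi < C <= T - lo) or C >= T:
            continue
        if exclude_intervening and j < i - 1:
            continue
        out.append((float(T), float(T - C)))
    return out


def conditional_average_corrected(
    trace: np.ndarray,
    selected: Sequence[tuple[float, float]],
    all_avg: TriggeredAverage,
    sample_rate: float,
    window: tuple[float, float] = (-0.02, 0.08),
    baseline_window: tuple[float, float] = (-0.02, -0.002),
    ensemble_correction: bool = False,
    stim_rate: float | None = None,
    dead_time: float = 0.003,
    response_start: float = 0.002,
) -> TriggeredAverage:
    """Conditioned triggered average, corrected for the conditioning response.

    Compiles the average over the selected triggers, then subtracts the
    all-stimulus average shifted by each trigger's own conditioning lag
    (baseline-referenced, averaged over triggers). Shifting is done on the
    sample grid; a lag requiring support beyond ``all_avg`` raises
    :class:`SupportError`.

    With ``ensemble_correction`` an additional term compensates the fact that
    the shifted all-stimulus average embodies the *renewal-rate* expectation
    of stimuli following the conditioner, whereas the selected ensemble
    forbids stimuli between conditioner and trigger. The missing expected
    background, ``stim_rate`` times the running integral of the unit response
    over the forbidden span, is restored using the all-stimulus average
    itself as the unit-response estimate. This matters for curve estimation
    at ordinary stimulus rates; it is off by default so the plain algebraic
    subtraction is available unchanged.
    """
    if not selected:
        raise InsufficientDataError("no selected triggers")
    trace = np.asarray(trace, dtype=float)
    fs = sample_rate
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    all_lo = int(round(all_avg.lags[0] * fs))
    n_all = len(all_avg.mean)

    acc = np.zeros(i_hi - i_lo, dtype=float)
    corr = np.zeros(i_hi - i_lo, dtype=float)
    used = 0
    base_rel = all_avg.mean - all_avg.baseline
    if ensemble_correction:
        if stim_rate is None:
            raise ConfigurationError("ensemble_correction requires stim_rate")
        from scipy.ndimage import uniform_filter1d

        # reconstruct the background from the synaptic response only: the
        # stimulus artifact and field average to ~zero mass but their sharp
        # oscillation would alias through the integration bounds
        khat = np.where(all_avg.lags >= response_start, base_rel, 0.0)
        khat_int = np.concatenate([[0.0], np.cumsum(khat) / fs])
        d_steps = int(round(dead_time * fs))
        # soften the integration bounds over the dead-time scale: the renewal
        # density of neighbouring stimuli rises smoothly, and hard bounds
        # would alias the oscillatory stimulus artifact into the correction
        if d_steps > 1:
            khat_int = uniform_filter1d(khat_int, size=d_steps, mode="nearest")
        g = np.arange(i_lo, i_hi) - all_lo

        def _K(idx: np.ndarray) -> np.ndarray:
            return khat_int[np.clip(idx, 0, n_all)]

    for T, lag in selected:
        c = int(round(T * fs))
        if c + i_lo < 0 or c + i_hi > len(trace):
            continue
        shift = c - int(round((T - lag) * fs))  # conditioning lag in samples
        j0 = i_lo + shift - all_lo
        j1 = i_hi + shift - all_lo
        if j0 < 0 or j1 > n_all:
            raise SupportError(
                f"conditioning lag {lag * 1e3:.1f} ms needs all-average support "
                f"beyond [{all_avg.lags[0]:.3f}, {all_avg.lags[-1]:.3f}] s"
            )
        acc += trace[c + i_lo : c + i_hi]
        corr += base_rel[j0:j1]
        if ensemble_correction:
            # restore the background the all-stimulus average carries but the
            # two-pulse ensemble lacks (no stimuli between conditioner and
            # trigger), so conditioned and unconditioned averages are measured
            # against the same background shape:
            #   corrected += rate * (Khat(tau + lag - dead) - Khat(tau + dead))
            # with Khat the running integral of the unit response.
            corr += stim_rate * (_K(g + d_steps) - _K(g + shift - d_steps))
        used += 1
    if used == 0:
        raise InsufficientDataError("no selected trigger has a complete window")
    mean = acc / used - corr / used
    lags = np.arange(i_lo, i_hi) / fs
    bmask = (lags >= baseline_window[0]) & (lags < baseline_window[1])
    if not bmask.any():
        raise ConfigurationError("baseline window lies outside the averaging window")
    return TriggeredAverage(
        lags=lags,
        mean=mean,
        n_triggers=used,
        baseline=float(mean[bmask].mean()),
        baseline_window=baseline_window,
        sample_rate=fs,
    )


def _smoothed(avg: TriggeredAverage, smooth_ms: float) -> TriggeredAverage:
    """Boxcar-smooth an average (no-op for smooth_ms <= 0)."""
    if smooth_ms <= 0:
        return avg
    from scipy.ndimage import uniform_filter1d

    n = max(1, int(round(smooth_ms * 1e-3 * avg.sample_rate)))
    if n <= 1:
        return avg
    mean = uniform_filter1d(avg.mean, size=n, mode="nearest")
    bmask = (avg.lags >= avg.baseline_window[0]) & (avg.lags < avg.baseline_window[1])
    return TriggeredAverage(
        lags=avg.lags,
        mean=mean,
        n_triggers=avg.n_triggers,
        baseline=float(mean[bmask].mean()),
        baseline_window=avg.baseline_window,
        sample_rate=avg.sample_rate,
    )


def conditioning_curve(
    recording: Recording,
    nerve: str,
    windows: Sequence[ConditioningWindow] | None = None,
    axis_mode: str = "interval",
    search_window: tuple[float, float] = (0.002, 0.050),
    threshold_uv: float = 50.0,
    min_triggers: int = 10,
    exclude_intervening: bool = True,
    avg_window: tuple[float, float] = (-0.02, 0.08),
    baseline_window: tuple[float, float] = (-0.02, -0.002),
    ensemble_correction: bool = True,
    smooth_ms: float = 0.8,
    artifact_window: tuple[float, float] | None = (0.0, 0.002),
) -> ConditioningCurve:
    """Conditioned IPSP amplitude (percent of unconditioned) per window.

    ``axis_mode="interval"`` places each point at the window-center interval;
    ``axis_mode="frequency"`` at its reciprocal (used for the long-range
    curve). The unconditioned IPSP must pass the detection threshold. The
    ensemble-rate background correction (see
    :func:`conditional_average_corrected`) is applied by default.

    Both the conditioned and the unconditioned average are boxcar-smoothed by
    ``smooth_ms`` before amplitude measurement: the free peak search over the
    IPSP window otherwise picks up an extreme-value bias proportional to each
    average's own noise level, which differs strongly between the
    all-stimulus average and the much smaller conditioned ensembles. The
    smoothing is identical for numerator and denominator, leaving the
    percentage unbiased. Each point's ``sem`` is the propagated measurement
    uncertainty, sqrt(2) x the conditioned average's baseline SD expressed in
    percent of the unconditioned amplitude.
    """
    if axis_mode not in ("interval", "frequency"):
        raise ConfigurationError("axis_mode must be 'interval' or 'frequency'")
    if windows is None:
        windows = long_range_windows() if axis_mode == "frequency" else short_range_windows()

    train = recording.train(nerve)
    trace = recording.intracellular
    fs = recording.sample_rate
    if artifact_window is not None:
        # remove stimulus artifact + antidromic field before averaging, as for
        # coherence: their images at the neighbour renewal density otherwise
        # contaminate both the conditioned and unconditioned backgrounds
        from renshaw.signal_prep import interpolate_stimulus_window

        trace = interpolate_stimulus_window(trace, train.times, artifact_window, fs)
    dead = train.config.dead_time
    max_shift = max(w.offset + w.width for w in windows)
    all_avg = triggered_average(
        trace,
        train.times,
        fs,
        window=(avg_window[0], avg_window[1] + max_shift + 2 * dead),
        baseline_window=baseline_window,
    )
    all_avg_s = _smoothed(all_avg, smooth_ms)
    uncond = measure_ipsp(all_avg_s, search_window, threshold_uv)
    if not uncond.detected:
        raise InsufficientDataError(
            f"unconditioned IPSP not detected ({uncond.amplitude_uv:.1f} µV "
            f"< {threshold_uv:.0f} µV)"
        )
    # second pass: a measurement window tight around the unconditioned IPSP
    # (conditioned IPSPs share its latency); the free peak search over the
    # full window would otherwise add an extreme-value bias that grows as the
    # conditioned ensembles shrink. Applied identically to conditioned and
    # unconditioned averages.
    measure_window = (
        max(search_window[0], uncond.onset_latency - 0.002),
        min(search_window[1], uncond.peak_latency + 0.003),
    )
    uncond = measure_ipsp(all_avg_s, measure_window, threshold_uv)

    points: list[CurvePoint] = []
    for w in windows:
        sel = select_conditioned_triggers(train, w, exclude_intervening)
        axis = w.center if axis_mode == "interval" else 1.0 / w.center
        if len(sel) < min_triggers:
            points.append(CurvePoint(w, axis, float("nan"), len(sel), float("nan")))
            continue
        cond = conditional_average_corrected(
            trace, sel, all_avg, fs, avg_window, baseline_window,
            ensemble_correction=ensemble_correction,
            stim_rate=len(train) / train.config.duration,
            dead_time=dead,
        )
        cond_s = _smoothed(cond, smooth_ms)
        m = measure_ipsp(cond_s, measure_window, threshold_uv)
        pct = 100.0 * m.amplitude_uv / uncond.amplitude_uv
        sem = float(
            100.0 * np.sqrt(2.0) * np.std(cond_s.baseline_samples()) * 1000.0
            / uncond.amplitude_uv
        )
        mean_lag = float(np.mean([lag for _, lag in sel]))
        points.append(CurvePoint(w, axis, pct, cond.n_triggers, mean_lag, sem))
    return ConditioningCurve(nerve, axis_mode, tuple(points), uncond.amplitude_uv)


def curve_significance(
    curves: Sequence[ConditioningCurve], q: float = 0.05
) -> pd.DataFrame:
    """Across motoneuron-nerve pairs: departure of each point from 100%.

    Per shared window, a two-sided one-sample t test of the amplitude
    percentages against 100, with Benjamini-Hochberg acceptance at FDR ``q``
    across the windows of this curve set. Error bars are reported as 2 x SEM
    (SEM with an n-1 denominator).
    """
    if len(curves) < 2:
        raise InsufficientDataError("need >= 2 curves")
    ref = curves[0]
    for c in curves[1:]:
        if len(c.points) != len(ref.points) or any(
            p.window != rp.window for p, rp in zip(c.points, ref.points)
        ):
            raise ConfigurationError("curves must share window definitions")
    mat = np.array([[p.amplitude_pct for p in c.points] for c in curves])  # pairs x windows
    rows = []
    for j, rp in enumerate(ref.points):
        col = mat[:, j]
        col = col[np.isfinite(col)]
        n = len(col)
        if n >= 2:
            t, p = stats.ttest_1samp(col, 100.0)
            sem = float(np.std(col, ddof=1) / np.sqrt(n))
            mean = float(col.mean())
        else:
            p, sem, mean = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "axis_value": rp.axis_value,
                "window_offset_ms": rp.window.offset * 1e3,
                "window_width_ms": rp.window.width * 1e3,
                "mean_pct": mean,
                "sem": sem,
                "err95": 2.0 * sem if np.isfinite(sem) else float("nan"),
                "n": n,
                "p": float(p) if np.isfinite(p) else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    finite = df["p"].notna().to_numpy()
    accepted = np.zeros(len(df), dtype=bool)
    if finite.any():
        accepted[finite] = benjamini_hochberg(df.loc[finite, "p"].to_numpy(), q)
    df["accepted"] = accepted
    return df


def linear_prediction_coherence(
    all_avg: TriggeredAverage,
    train: StimulusTrain,
    config: CoherenceConfig | None = None,
    n_samples: int | None = None,
) -> CoherenceSpectrum:
    """Coherence expected under linear IPSP summation.

    Convolves the binarized train with the unconditioned average response
    (post-stimulus part, baseline-referenced) and computes the coherence of
    that synthetic membrane signal against the train — the spectrum a
    perfectly linear transmission would produce.
    """
    from scipy.signal import fftconvolve

    config = config or CoherenceConfig()
    fs = config.sample_rate
    if n_samples is None:
        n_samples = int(round(train.config.duration * fs))
    s = binarize_train(train, fs, n_samples)
    post = all_avg.lags >= 0
    kernel = (all_avg.mean - all_avg.baseline)[post]
    predicted = fftconvolve(s, kernel)[:n_samples]
    return coherence_spectrum(s, predicted, config)
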