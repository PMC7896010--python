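"""From raw traces to measured quantities.

Artifact-window interpolation, stimulus-triggered averaging, IPSP
onset-to-peak amplitude with the 50 µV detection rule, AHP duration, and
motoneuron categorization by the most distal antidromically responding nerve.

Conventions: lag 0 is stimulus onset; windows are half-open ``[start, end)``
in seconds; sample indexing is 0-based; triggers whose peri-stimulus window
falls outside the trace are dropped, not padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from renshaw.errors import ConfigurationError, InsufficientDataError

__all__ = [
    "TriggeredAverage",
    "IPSPMeasurement",
    "AHPMeasurement",
    "NERVE_VOCABULARY",
    "CATEGORIES",
    "interpolate_stimulus_window",
    "triggered_average",
    "measure_ipsp",
    "measure_ahp",
    "classify_motoneuron",
]

#: Nerves implanted in the experimental protocol.
NERVE_VOCABULARY = frozenset(
    {
        "radial_axilla",
        "musculocutaneous",
        "ulnar_arm",
        "median_arm",
        "deep_radial",
        "median_wrist",
        "ulnar_wrist",
    }
)

CATEGORIES = (
    "intrinsic_hand",
    "forearm_flexor",
    "forearm_extensor",
    "arm_extensor",
    "unidentified",
)


@dataclass(frozen=True)
class TriggeredAverage:
    """Average of peri-trigger trace segments on a uniform lag grid."""

    lags: np.ndarray          # seconds relative to trigger
    mean: np.ndarray          # millivolts
    n_triggers: int
    baseline: float           # millivolts, mean over the baseline window
    baseline_window: tuple[float, float]
    sample_rate: float

    def __post_init__(self) -> None:
        if self.n_triggers < 1:
            raise InsufficientDataError("TriggeredAverage needs >= 1 trigger")

    def baseline_samples(self) -> np.ndarray:
        b0, b1 = self.baseline_window
        mask = (self.lags >= b0) & (self.lags < b1)
        return self.mean[mask]

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        w0, w1 = window
        return (self.lags >= w0) & (self.lags < w1)


@dataclass(frozen=True)
class IPSPMeasurement:
    """Onset-to-peak IPSP amplitude and the detection decision."""

    amplitude_uv: float
    onset_latency: float
    peak_latency: float
    detected: bool
    threshold_uv: float = 50.0

    def __post_init__(self) -> None:
        if self.onset_latency > self.peak_latency:
            raise ValueError("onset must not follow the peak")


@dataclass(frozen=True)
class AHPMeasurement:
    """Post-spike after-hyperpolarization summary."""

    half_width: float
    trough_mv: float
    prespike_level_mv: float
    no_hyperpolarization: bool = False


def interpolate_stimulus_window(
    trace: np.ndarray,
    stim_times: Sequence[float] | np.ndarray,
    window: tuple[float, float],
    sample_rate: float,
) -> np.ndarray:
    """Replace a post-stimulus window with a straight line (artifact removal).

    For each stimulus, samples in ``[t + window[0], t + window[1])`` are
    replaced by the line joining the last sample before the window and the
    first sample after it. Overlapping windows from successive stimuli are
    merged. Stimuli whose window has no flanking sample on either side are
    skipped (counted in a warning).
    """
    w0, w1 = window
    if w0 < 0:
        raise ConfigurationError("window start must be >= 0 (post-stimulus)")
    if w1 <= w0:
        raise ConfigurationError("window end must exceed window start")
    out = np.asarray(trace, dtype=float).copy()
    n = len(out)
    stim = np.sort(np.asarray(stim_times, dtype=float))
    if stim.size == 0:
        return out

    starts = np.round((stim + w0) * sample_rate).astype(int)
    stops = np.round((stim + w1) * sample_rate).astype(int)
    # merge overlapping / abutting windows
    merged: list[list[int]] = []
    for a, b in zip(starts, stops):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    skipped = 0
    for a, b in merged:
        if a - 1 < 0 or b >= n:
            skipped += 1
            continue
        if b == a:
            continue
        line = np.linspace(out[a - 1], out[b], b - a + 2)
        out[a:b] = line[1:-1]
    if skipped:
        warnings.warn(
            f"interpolate_stimulus_window: skipped {skipped} window(s) at trace edges",
            stacklevel=2,
        )
    return out


def triggered_average(
    trace: np.ndarray,
    triggers: Sequence[float] | np.ndarray,
    sample_rate: float,
    window: tuple[float, float] = (-0.02, 0.08),
    baseline_window: tuple[float, float] = (-0.02, -0.002),
) -> TriggeredAverage:
    """Stimulus-triggered average of ``trace`` over complete segments.

    ``window`` and ``baseline_window`` are lag intervals relative to the
    trigger (negative = before). Triggers whose window exceeds the trace are
    dropped.
    """
    trace = np.asarray(trace, dtype=float)
    trig = np.asarray(triggers, dtype=float)
    if baseline_window[1] > 0 or baseline_window[0] >= baseline_window[1]:
        raise ConfigurationError("baseline window must precede lag 0")
    i_lo = int(round(window[0] * sample_rate))
    i_hi = int(round(window[1] * sample_rate))
    if i_hi <= i_lo:
        raise ConfigurationError("window end must exceed window start")
    centers = np.round(trig * sample_rate).astype(int)
    ok = (centers + i_lo >= 0) & (centers + i_hi <= len(trace))
    centers = centers[ok]
    if centers.size == 0:
        raise InsufficientDataError("no trigger has a complete peri-stimulus window")
    offsets = np.arange(i_lo, i_hi)
    # accumulate rather than stacking all segments: the averaging window can be
    # long (conditional-averaging corrections need support out to ~1 s)
    acc = np.zeros(offsets.size, dtype=float)
    for c in centers:
        acc += trace[c + i_lo : c + i_hi]
    mean = acc / centers.size
    lags = offsets / sample_rate
    bmask = (lags >= baseline_window[0]) & (lags < baseline_window[1])
    if not bmask.any():
        raise ConfigurationError("baseline window lies outside the averaging window")
    baseline = float(mean[bmask].mean())
    return TriggeredAverage(
        lags=lags,
        mean=mean,
        n_triggers=int(centers.size),
        baseline=baseline,
        baseline_window=baseline_window,
        sample_rate=sample_rate,
    )


def measure_ipsp(
    avg: TriggeredAverage,
    search_window: tuple[float, float] = (0.001, 0.050),
    threshold_uv: float = 50.0,
    k_sd: float = 2.0,
) -> IPSPMeasurement:
    """Onset-to-peak amplitude of the IPSP in a triggered average.

    The peak is the most negative deflection relative to baseline within
    ``search_window``; the onset is the last pre-peak sample at which the
    average lies inside the baseline band ``baseline - k_sd * SD(baseline)``.
    Responses smaller than ``threshold_uv`` are flagged as not detected.
    """
    mask = avg.window_mask(search_window)
    if not mask.any():
        raise ConfigurationError("search window lies outside the average")
    idx = np.flatnonzero(mask)
    seg = avg.mean[idx]
    rel = seg - avg.baseline
    i_min = int(np.argmin(rel))
    if rel[i_min] >= 0:
        t0 = float(avg.lags[idx[0]])
        return IPSPMeasurement(0.0, t0, t0, False, threshold_uv)
    peak_i = idx[i_min]
    peak_latency = float(avg.lags[peak_i])

    sd = float(np.std(avg.baseline_samples()))
    band = avg.baseline - k_sd * sd
    # walk back from the peak to the last sample at/above the baseline band
    onset_i = idx[0]
    for j in range(peak_i, idx[0] - 1, -1):
        if avg.mean[j] >= band:
            onset_i = j
            break
    onset_latency = float(avg.lags[onset_i])
    amplitude_uv = float((avg.mean[onset_i] - avg.mean[peak_i]) * 1000.0)
    amplitude_uv = max(amplitude_uv, 0.0)
    return IPSPMeasurement(
        amplitude_uv=amplitude_uv,
        onset_latency=onset_latency,
        peak_latency=peak_latency,
        detected=amplitude_uv >= threshold_uv,
        threshold_uv=threshold_uv,
    )


def measure_ahp(
    avg_spike: TriggeredAverage,
    mode: str = "half_recovery",
) -> AHPMeasurement:
    """Duration of the after-hyperpolarization in a spike-triggered average.

    ``mode="half_recovery"`` (default): total time the potential spends below
    the half-depth level ``prespike - 0.5 * (prespike - trough)``, i.e. the
    width at half maximum of the AHP. ``mode="time_to_half"``: time from the
    end of the spike (first post-peak return to the prespike level) until the
    potential first recovers above the half-depth level.
    """
    if mode not in ("half_recovery", "time_to_half"):
        raise ConfigurationError(f"unknown AHP mode {mode!r}")
    prespike = avg_spike.baseline
    post = avg_spike.lags >= 0
    seg = avg_spike.mean[post]
    lags = avg_spike.lags[post]
    spike_i = int(np.argmax(seg))
    after = seg[spike_i:]
    after_lags = lags[spike_i:]
    trough = float(after.min())
    if trough >= prespike:
        return AHPMeasurement(0.0, trough, prespike, no_hyperpolarization=True)
    half_level = prespike - 0.5 * (prespike - trough)
    below = after < half_level
    dt = 1.0 / avg_spike.sample_rate
    if mode == "half_recovery":
        half_width = float(below.sum() * dt)
        return AHPMeasurement(half_width, trough, prespike)
    # time_to_half: from spike end (first return to prespike level) to recovery
    returned = np.flatnonzero(after <= prespike)
    spike_end_i = int(returned[0]) if returned.size else 0
    rec = np.flatnonzero(below[spike_end_i:])
    if rec.size == 0:
        return AHPMeasurement(0.0, trough, prespike, no_hyperpolarization=True)
    last_below = spike_end_i + int(rec[-1])
    half_width = float(after_lags[last_below] + dt - after_lags[spike_end_i])
    return AHPMeasurement(half_width, trough, prespike)


def classify_motoneuron(antidromic_nerves: Iterable[str]) -> str:
    """Muscle-group category from the set of antidromically responding nerves.

    Applies the most-distal rule: any wrist nerve -> intrinsic_hand; else
    ulnar/median at the arm -> forearm_flexor; else deep radial ->
    forearm_extensor; else radial at the axilla -> arm_extensor; an empty set
    -> unidentified.
    """
    nerves = set(antidromic_nerves)
    unknown = nerves - NERVE_VOCABULARY
    if unknown:
        raise ConfigurationError(f"unknown nerve label(s): {sorted(unknown)}")
    if nerves & {"median_wrist", "ulnar_wrist"}:
        return "intrinsic_hand"
    if nerves & {"ulnar_arm", "median_arm"}:
        return "forearm_flexor"
    if "deep_radial" in nerves:
        return "forearm_extensor"
    if "radial_axilla" in nerves:
        return "arm_extensor"
    return "unidentified"
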