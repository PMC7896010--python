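# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable option existed.

## Synthetic stimulus trains

Motor-nerve stimulation is modelled as a Poisson process with a refractory
dead time: inter-event intervals are `dead_time + Exponential(mean =
1/mean_rate − dead_time)`. Defaults are a 10 Hz mean rate and a 3 ms dead
time. Implementing the dead time by interval shifting (rather than by
thinning a plain Poisson process) makes the achieved long-run rate equal the
configured rate exactly; the alternative reading — 10 Hz before deletion —
would give a slightly lower achieved rate. All randomness in the package
flows from one integer seed through named, counter-based stream splits
(`renshaw._rng.child_rng`), so adding a stream never perturbs existing ones
and every channel and train is independently reproducible.

## Synthetic recordings

A recording is the resting potential (−70 mV) plus, per stimulus: a one-cycle
sine **artifact** (default 2 mV peak, 1 ms), a brief negative **antidromic
field** (default 100 µV, 0.4–1.4 ms post-stimulus), and — for nerves with a
configured connection — a **recurrent IPSP**. The IPSP kernel is a
difference of exponentials (default latency 2.5 ms, rise τ 1.5 ms, decay τ
8 ms), normalized so its most negative point equals the configured amplitude
(default 200 µV; the deflection is negative-going). IPSP shape and latency
are package defaults, not measured values. Optionally an antidromic spike
(Gaussian, 60 mV) followed by an alpha-shaped AHP is added for the
antidromically activated nerve. Membrane noise is Gaussian at the sample rate
(default SD 100 µV), with an optional one-pole low-pass. Traces are stored in
millivolts at 25 kSamples/s; amplitudes are configured and reported in
microvolts.

Nonlinear IPSP summation is phenomenological: each IPSP's amplitude is
multiplied by

```
(1 − a_s·exp(−Δ/τ_s)) · (1 − a_l·exp(−(Δ − c)²/(2w²)))
```

where Δ is the interval since the **most recent** prior stimulus of the same
nerve. The first factor is paired-pulse depression (defaults a_s = 0.6,
τ_s = 8 ms, recovering over a few tens of milliseconds); the second is a
suppression band for IPSPs recurring around 6 Hz (defaults a_l = 0.25,
c = 167 ms, w = 45 ms, covering roughly 5–7 Hz). Only the IPSP term is
scaled — never artifact or field. Depending only on the single most recent
prior stimulus is the simplest model consistent with a two-pulse conditioning
analysis; it also means the generator produces *no* conditioning effect when
another stimulus intervenes between conditioner and trigger, which is why the
conditioning analysis excludes such triggers by default (see below).

What the generator does **not** emulate: electrode penetration artifacts,
bridge-balance errors, slow drift, spike-rate adaptation, or any mechanistic
synaptic-resource dynamics. Passing tests on this synthetic data therefore
validate the estimators against a known ground truth under stationary,
additive-noise conditions; they do not certify behaviour under slow
nonstationarities that real recordings can contain.

## Triggered averaging and IPSP measurement

Lag 0 is stimulus onset; windows are half-open `[start, end)`; sample
indexing is 0-based; triggers whose peri-stimulus window would leave the
trace are dropped, not padded. The stimulus artifact (and field) can be
removed by replacing a per-stimulus window with the straight line joining the
samples on either side; overlapping windows from successive stimuli are
merged into one.

IPSP amplitude is measured from a triggered average as onset-to-peak: the
peak is the most negative deflection relative to the baseline (mean over a
pre-trigger window, default −20 to −2 ms) within a search window (default
1–50 ms, 2–50 ms in the conditioning analysis); the onset is the last
pre-peak sample inside the baseline band `baseline − k·SD(baseline samples)`
with k = 2 by default. The band-crossing onset rule is a package choice made
for robustness on noisy averages — the underlying experimental definition
("onset to peak") does not specify an algorithm — and k is exposed. Responses
smaller than 50 µV are flagged as not detected. Note one consequence of the
rule: the measured amplitude is smaller than baseline-to-peak by about
k·SD of the average's own noise, so averages with few sweeps read slightly
low; the conditioning-curve estimator compensates for this explicitly (see
below).

AHP duration is the width at half maximum: the time spent below
`prespike − 0.5·(prespike − trough)` after the spike. An alternative
definition (time from spike end until recovery above the half level) is
available behind a switch, since the two are not equivalent on asymmetric
waveforms.

Motoneuron categories follow the most-distal rule over the implanted-nerve
vocabulary: any wrist nerve → intrinsic hand; else ulnar/median at the arm →
forearm flexor; else deep radial → forearm extensor; else radial at the
axilla → arm extensor; no antidromic response → unidentified.

## Coherence and phase

The stimulus train is binarized at the trace sample rate (a one in the bin
containing each onset; the 3 ms dead time guarantees one event per 40 µs bin
at most). Both signals are cut into non-overlapping windows of 2¹⁴ = 16,384
samples (1.53 Hz resolution at 25 kHz), the trailing partial window is
discarded, each window is demeaned (preventing the DC bin and the mean
stimulus rate from dominating; exposed as a switch) and left untapered
(rectangular window, matching the plain segment method; a Hann taper is
available). With segment transforms Xᵢ, Yᵢ:

```
coh(f)   = |Σᵢ conj(Xᵢ)·Yᵢ|² / (Σᵢ|Xᵢ|²·Σᵢ|Yᵢ|²)
phase(f) = arg Σᵢ conj(Xᵢ)·Yᵢ
```

**Sign convention** (x = stimulus, y = membrane potential): delaying y by d
seconds changes the phase by −2πfd at every frequency, so a positive
transmission delay gives a negative phase-frequency slope, and the delay
estimate is −slope/2π. A negative-going (inhibitory) response contributes an
extra π, which is why loop phases near 10 Hz land in (0, π).

The significance limit for a single spectrum of L segments at level α is
`1 − α^(1/(L−1))`; its type-I calibration is verified by simulation for
L ∈ {5, 20, 100}. Averaging across recording pairs takes the per-frequency
arithmetic mean of coherence; the averaged spectrum's significance limit is
recomputed with L equal to the total segment count — the natural pooled
extension of the single-spectrum formula, used in place of any more exact
pooled correction. The averaged spectrum's phase at each bin is the circular
mean over the spectra whose own coherence exceeds their own limit. Band
summaries pool the phase of every significant (spectrum, bin) pair in the
band and report the circular mean plus rose-plot counts.

The phase-slope delay unwraps the phase across all bins in the fit range
(default 20–100 Hz, above the low-frequency curvature), fits an ordinary
least-squares line restricted to significant bins, and converts the slope and
its t-based confidence interval to seconds. On noise-free constructed delays
the estimator is exact to well under a microsecond.

## Conditional averaging (nonlinear summation)

Triggers T are selected that have a conditioning stimulus C with
`T − C ∈ [offset, offset + width)`; the most recent qualifying C defines the
lag. Triggers with any other stimulus between C and T are **excluded** by
default so each conditioned average reflects a clean two-pulse interaction
(exposed as a flag); with the generator's most-recent-prior nonlinearity this
exclusion is also what makes the conditioning lag the effective interval.
One consequence: at long offsets the probability that no stimulus intervenes
decays as e^(−λ·offset), so windows centred beyond roughly 500 ms at 10 Hz
yield too few triggers and are reported as empty points.

The conditioned average is corrected by subtracting, per trigger, the
all-stimulus average shifted by that trigger's own conditioning lag
(per-trigger shifting is unbiased for any within-window lag distribution).
Two refinements beyond the plain subtraction proved necessary for unbiased
curve estimation at ordinary stimulus rates, and both are documented package
choices:

1. **Ensemble-rate background correction** (on by default in
   `conditioning_curve`, opt-in in `conditional_average_corrected`). The
   shifted all-stimulus average embodies the renewal-rate expectation of
   stimuli *following* the conditioner, but the selected two-pulse ensemble
   forbids stimuli between C and T. Equating the corrected average's
   background to the unconditioned average's background requires adding
   `rate·[K(τ + lag − dead) − K(τ + dead)]`, where K is the running integral
   of the unit response (estimated from the all-stimulus average itself,
   restricted to lags after the artifact/field span) and dead is the dead
   time. The integration bounds are softened over the dead-time scale, since
   the true neighbour density rises smoothly rather than as a step. Without
   this term the apparent paired-pulse recovery time constant comes out
   roughly double the generator's value at 10 Hz with ~40 ms IPSPs.
2. **Matched measurement.** The stimulus artifact window is interpolated out
   of the trace first (its images at the neighbour renewal density otherwise
   contaminate both backgrounds); both the conditioned and the unconditioned
   average are boxcar-smoothed by 0.8 ms before measurement (the free peak
   search otherwise collects an extreme-value bias proportional to each
   average's own noise, which differs strongly between the all-stimulus
   average and the much smaller conditioned ensembles); and after measuring
   the unconditioned IPSP once, both are re-measured in a tight window around
   its onset and peak, which the conditioned IPSPs share. Each point's SEM is
   the propagated measurement uncertainty, √2 × the conditioned average's
   baseline SD in percent of the unconditioned amplitude.

Amplitudes are expressed as percentages of the unconditioned IPSP. Because
the unconditioned (all-stimulus) average is itself depressed by the mean
nonlinearity factor, a fully recovered conditioned IPSP sits slightly
*above* 100%; parameter-recovery fits therefore include a free asymptote.
Short-range curves default to 5 ms windows at offsets 0–45 ms; long-range
curves use 100 ms windows with centres placed geometrically from 53 ms to
1 s and a frequency axis equal to the reciprocal of the window centre.
Across motoneuron-nerve pairs, each window is tested against 100% with a
two-sided one-sample t test; Benjamini–Hochberg acceptance at 5% FDR is
applied separately per curve set (SEM uses n−1; error bars are 2×SEM).

The linear-prediction comparison convolves the binarized train with the
unconditioned average response and computes its coherence with the train —
the spectrum transmission would show if IPSPs summed linearly. Note an
estimator property: convolution tails crossing the non-overlapping window
boundaries keep even the noise-free prediction's coherence slightly below 1,
increasingly so where the kernel's transfer magnitude is small; gap
comparisons between measured and predicted coherence are therefore made
within bands, against matched controls where a specific generator mechanism
is being isolated.

## Population statistics

The resampling unit is the motoneuron (not the motoneuron-nerve pair), to
respect within-cell correlation. Grouping by category, a motoneuron with
detected IPSPs from several nerves contributes the mean of those amplitudes
once; grouping by nerve, each motoneuron appears once per nerve. Records
flagged as not measurable (an antidromic spike obscured the IPSP — the
homonymous-connection caveat) are excluded from every measure. The product
measure amplitude × incidence/100 is identical to the zero-inclusive mean
amplitude; this identity is tested to 10⁻¹² on random cohorts.

Bootstrap CIs are percentile intervals over motoneuron resamples (default
10,000); Monte-Carlo category comparison draws same-sized subsets without
replacement from the full cohort and doubles the smaller tail with add-one
smoothing, so p is never exactly 0 and equals 1 when the category is the
whole cohort. The binomial proportion test is exact, two-sided by tail
doubling (the minimum-likelihood convention gives similar but not identical
values). Benjamini–Hochberg returns acceptance flags only — no adjusted
p-values — with m equal to the number of comparisons in the run; m is
recorded in the output rather than hard-coded, since the appropriate
comparison count depends on the analysis at hand.

## Loop model

The recorded motoneuron is a passive two-compartment cell (soma: 1800 pF,
300 nS leak; dendrite: 2400 pF, 400 nS; coupling 2700 nS, giving ~0.9
dendrite-to-soma steady-state attenuation; rest −70 mV; somatic input
resistance ~2.6 MΩ, membrane time constant 6 ms). Each of its 20 Renshaw
cells is an exponential integrate-and-fire unit (τ_m = 8 ms, threshold
−50 mV with 1 mV per-cell jitter, slope factor 2 mV, reset −65 mV, 1 ms
absolute refractory period). A nerve stimulus delivers, after a 1.5 ms axonal
delay, a synchronized compound EPSP conductance to every Renshaw cell —
50 converging motor axons × a unitary alpha conductance whose time-to-peak
is the configured "rise time". The compound peak is charge-normalized across
rise times (peak ∝ 1/rise), so 1, 4 and 8 ms EPSPs inject the same
conductance charge per volley and differ only in time course. Renshaw spikes
reach the motoneuron dendrite after a 1 ms synaptic delay as glycinergic
alpha conductances (τ 3 ms, reversal −80 mV). Somatic membrane noise
(default 50 µV SD, low-passed at 100 Hz) is added to the output.

Because the protocol drives the motor axons directly and the recorded cell
rests below threshold, the other motoneurons of the pool cannot influence
it; the pool sizes enter only through the compound volley, making the
reduced simulation (one motoneuron + its Renshaw cells) an exact reduction
of the full pool under this protocol.

**Calibration.** The two free synaptic strengths (unitary EPSP peak 2 nS at
1 ms rise; unitary glycine peak 1.2 nS) were calibrated once, with
`scripts/calibrate_loop.py`, against two physiological criteria only: a
single volley elicits a Renshaw burst of 2–5 spikes per cell, and the
compound somatic IPSP lies in the 100–500 µV range, for every rise time in
{1, 4, 8} ms. The 8–12 Hz coherence phases are then *measured outcomes* of
the calibrated model, not tuned quantities.

**Integration.** Fixed-step exponential updates for all conductance states
(the alpha function is the exact solution of a two-state linear system) and
forward Euler for the membrane equations at dt = 20 µs, exactly two steps
per 25 kHz output sample (dt must not exceed the output interval, and must
divide it). The first second is discarded while conductances settle.
Halving dt changes the 8–12 Hz band phase by less than 0.02 rad; inserting
an extra 2 ms delay into the loop shifts the band phase by −2πf·d within
0.02 rad, confirming the phase bookkeeping; potentials beyond ±200 mV abort
with a stability error.

**Phase behaviour.** With everything else fixed, a longer EPSP conductance
rise time means a later Renshaw threshold crossing and a longer effective
loop lag, so the 8–12 Hz coherence phase *decreases* from π as the rise time
grows: the calibrated reference model gives ≈2.12 rad (1 ms), ≈1.77 rad
(4 ms) and ≈1.37 rad (8 ms) at 400 s (stable to ±0.02 rad across seeds).
This monotone decrease is a direct consequence of causal filtering — any
added lag (slower conductance, extra delay, slower membrane) moves the phase
the same way — and the delay-insertion audit above demonstrates it
quantitatively. The package reports all three values and treats the ordering
as a model property to be measured, not asserted.

**Scale.** Simulations used for validation run at reduced duration (100–400 s
rather than the 1001 s reference); the band-phase estimate changes by less
than 0.05 rad between 100 s and 400 s, and the acceptance script uses 400 s.

## Problem sizes used by the checks

Chosen so each check is statistically decisive: triggered-average recovery
at 10²–10⁴ sweeps; conditioning-curve recovery on a clear test cell (350 µV
IPSP, 125 µV noise, 10⁴ stimuli), with the depression parameters fitted by
weighted least squares (per-point SEM weights, free asymptote); coherence
calibration at L ∈ {5, 20, 100} windows; delay recovery over 20 seeded 60 s
runs; bootstrap coverage over 1000 cohorts of 96 motoneurons with 1000
resamples each; permutation-null uniformity over 500 cohorts at 499
permutations.

## Known limitations

- The generator's nonlinearity is phenomenological (amplitude scaling by the
  most recent prior interval); it reproduces conditioning curves and
  band-structured coherence gaps but is not a synaptic-resource or
  conductance mechanism, and its low-rate suppression also injects broadband
  amplitude jitter whose coherence cost grows with frequency.
- The band-crossing onset rule couples measured amplitude to the average's
  noise level; the conditioning pipeline compensates, but single
  low-sweep-count measurements read a few percent low.
- The pooled significance limit for averaged spectra (L = total segments) is
  an extension of the single-spectrum formula, not an exact pooled
  correction.
- The Renshaw cell has no Renshaw–Renshaw inhibition, no I_h and no
  adaptation; the recorded motoneuron is passive. The model is a transfer
  model of the stimulated loop at rest, not of an actively firing pool.
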