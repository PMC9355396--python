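# Methods

This note documents the models, defaults and numerical choices behind
`phytoephys`, and what the synthetic benchmark does and does not establish
about real recordings.

## Signal templates

**Venus-flytrap action potential.** Surface APs are modeled as
negative-first deflections (depolarization = downward), because the
benchmark statistics are ordered that way (minimum amplitude and maximal
down slope first). The noise-free template is a product of two sigmoids —
a fast sigmoidal drop with time constant `rise_tau_s` (default 0.08 s) and
a slower sigmoidal recovery with `fall_tau_s` (default 0.5 s, plateau span
2·`fall_tau_s`) — normalized so the sampled minimum equals exactly
−`amplitude_mV` (default 40 mV). The product form guarantees a single
global extremum, a leading edge that is the steepest part of the trace
(well-posed derivative-minimum alignment), and well-defined half-width and
slope statistics. `jitter` (default 0.1) multiplies amplitude and both time
constants by independent `1 + jitter·N(0,1)` factors per trial; this is
what makes slope-vs-amplitude regressions informative.

**Wound-activated surface potential change (WASP).** Zero baseline until
`latency_s` (default 1 s) after laser-on, then
`(1 − e^(−t/depol_tau)) · e^(−t/recovery_tau)` (defaults 2 s and 8 s),
negative-going, normalized to −`amplitude_mV` (default 30 mV). A pure
exponential tail never recrosses zero derivative, which would make the
operational duration definition (first derivative zero after the extremum)
ill-posed; real wound responses terminate. The template therefore includes
a small Gaussian "rebound" bump (`rebound_frac`, default 6% of peak,
centred at 2.5·`recovery_tau`, width 0.5·`recovery_tau`) that ends the
recovery at a finite, well-conditioned time — with the defaults, total
duration ≈ 23 s from laser-on. `tail_variability` (default 0.25) is the
relative s.d. of `recovery_tau` across trials and additionally scales a
0.2 Hz-low-passed roughness confined to the tail, so recovery duration
varies strongly across trials (s.d. of several seconds) while the rising
phase stays stereotyped.

## Noise model

Additive, in volts at the plant surface:

* Gaussian sensor noise, `baseline_sd` = 1.5 mV;
* baseline wander: white noise low-pass filtered at `drift_fc_hz`
  (0.005 Hz, generated on a coarse grid and interpolated), r.m.s.
  `drift_amp` = 0.5 mV — this is what the 0.01 Hz highpass removes;
* 50 Hz mains, amplitude 4.5 mV, multiplied by `cage_attenuation` = 0.01
  (40 dB, typical of a shielded enclosure) when the Faraday cage is closed;
* 40 Hz laser artifact, amplitude 2 mV, present only inside
  laser_on–laser_off windows.

Sessions acquire at 1 kHz (instruments sample faster than the 100 Hz
analysis rate, so the decimation stage is exercised) with 20 s of
pre-stimulus baseline.

## Device models and calibration

The OECT transfer curve is `I_D(V_GS) = −i_max·σ((V_th−V_GS)/s)` with
`i_max` = 1 mA, `V_th` = 0.3 V, `s` = 0.15 V: depletion-mode (on at
negative gate bias, dedoped by positive `V_GS`), single transconductance
peak `g_m = i_max/4s ≈ 1.67 mS` at `V_GS = V_th`, which is also the
operating point (`V_GS` = 0.3 V, `V_DS` = −0.4 V). The Bernards–Malliaras
linear-regime form would be an acceptable alternative behind the same
interface; the logistic was chosen for its smoothness and closed-form
derivative. Gate couplings: soil 1.0, plant surface 0.9, co-planar 0.0
(slightly better modulation with the gate in soil; no plant signal at all
with a co-planar gate, since the plant is then outside the transistor
circuit).

Noise entry is phenomenological, not mechanistic. Ambient interference
(drift + mains + laser) reaches the electrode output at susceptibility 1.0
on top of the Gaussian sensor floor; it reaches the OECT output referred
through `g_m` and scaled by susceptibility 0.005, on top of an intrinsic,
cage-independent current-noise floor of 46 nA. These four numbers were
calibrated analytically to the study conditions — an open-cage SNR near
1250 for the OECT and near 11 for the Ag/AgCl electrode, i.e. a gap of
about 40 dB:

* electrode baseline s.d. ≈ √(1.5² + 0.5² + (4.5/√2)²) ≈ 3.55 mV →
  SNR ≈ 40/3.55 ≈ 11;
* OECT signal ≈ g_m·40 mV ≈ 67 µA; noise ≈ √((0.005·g_m·3.22 mV)² + 46²)
  ≈ 53 nA → SNR ≈ 1250.

Because only the electrode's noise is mains-dominated, closing the cage
raises the electrode SNR roughly twofold while barely moving the OECT's,
so the device gap *shrinks* inside the cage (≈ 34 dB vs ≈ 39.5 dB) — the
qualitative cage interaction the benchmark reports. Sign convention:
depolarization = negative surface deflection; with g_m > 0 at bias the
OECT current mirrors the surface waveform.

## Preprocessing

* **Downsampling** uses polyphase resampling with line-extension padding
  (a large DC operating point such as the −0.5 mA OECT bias current must
  not ring at the record edges). Event times are stored in seconds and are
  rate-independent.
* **Highpass**: 2nd-order Bessel, 0.01 Hz, magnitude-normalized analog
  prototype discretized by the bilinear transform with prewarping at the
  corner, applied causally (single forward pass — instrument-like, not
  zero-phase; phase distortion at 0.01 Hz is negligible for ≥ 0.1 Hz
  content). Initial conditions assume the first sample's level has been
  applied forever, so a DC offset does not excite a multi-hundred-second
  start-up transient. Applied to APs only; a 0.01 Hz highpass would
  distort the WASP's tens-of-seconds tail.
* **Smoothing**: unit-area Gaussian kernel whose ±3σ support equals the
  stated window (σ = window/6), reflection at edges; 200 ms for APs,
  500 ms for WASPs. (The alternative window = FWHM convention would make
  the kernel ≈ 2.5× wider.)
* **Alignment**: APs on the global minimum of the central-difference first
  derivative, searched from 0.5 s before the stimulus event to 1 s before
  the record end (the benchmark does not state a window; ties break to the
  earliest sample, flat derivatives raise an error); WASPs on the laser-on
  event. Repeats within one trap are averaged before group statistics
  (N = 1 per trap).
* **Confidence bands**: mean ± 1.96·SEM pointwise.

Stage order is fixed: downsample → highpass → align → per-trap average →
smooth → features (APs); downsample → align-by-event → smooth → features
(WASPs). Whether highpass preceded alignment in the original workflow is
not documented; this package fixes highpass-before-alignment.

## Feature extraction

All amplitudes are relative to the mean of the pre-stimulus baseline
(minus a 1 s guard). Crossing times interpolate linearly between
bracketing samples. The AP up-slope is restricted to the segment between
the waveform minimum and its subsequent maximum.

**WASP duration** is the first zero of the first temporal derivative after
the extremum. At 100 Hz with 500 ms smoothing, the sample-scale derivative
of a tens-of-seconds tail is noise-dominated at any realistic SNR, so the
derivative is additionally trend-smoothed with a 2 s Gaussian window
(`derivative_smooth_s`, same window convention) before the crossing
search, and a crossing must persist ≥ 3 samples. If no crossing exists the
record-end time is returned with a `recovered=False` flag rather than a
fabricated value.

**SNR** is computed on the *raw* native-rate trace: the decimation
anti-alias filter (cutoff below 50 Hz at the 100 Hz target) would remove
the very mains component whose cage contrast the benchmark quantifies.
For the same reason spectral analyses (scalograms, narrowband power) use a
200 Hz copy, on which 50 Hz is still below Nyquist. The baseline window is
the full pre-stimulus segment minus a 1 s guard; the sample (n−1) standard
deviation is used, and a zero-variance baseline raises an error instead of
returning infinite SNR.

**Ground truth** for parameter-recovery checks is operational: the
noise-free template pushed through the identical chain and measured by the
identical extractor. The templates have no closed-form half-width or
duration, and an operational reference separates noise-induced error
(which the recovery criterion measures) from deterministic smoothing bias
(which affects template and trial identically).

## Spectral analysis

Complex Morlet wavelet (`cmor1.5-1.0`), log-spaced frequencies (default
0.1–50 Hz, 64 voices), magnitude normalized to a global maximum of 1 with
a zero-input guard. The wavelet family and frequency grid of the original
figures are not documented; any smooth analytic wavelet gives the same
ridge structure. Narrowband power is periodogram integration over
f₀ ± bw/2 as a fraction of total power.

## Statistics

Simple linear regression per device × cage group; slope equality is tested
by the F-test comparing `y ~ x + group` against `y ~ x * group` (the
pooled interaction test requires raw observations, so the comparison
consumes per-group (x, y) data rather than fitted summaries). The
factorial comparison is a two-way ANOVA (device × cage, with interaction)
using Type II sums of squares — appropriate for the unbalanced group sizes
of a real benchmark when the interaction is not assumed, and switchable to
Type III — followed by Tukey HSD with the Tukey–Kramer adjustment for
unequal n. Significant pairs are split into within-cage (device contrasts)
and within-device (cage contrasts) sets. An all-equal input returns a
`no_variance` flag instead of a 0/0 F statistic. The Tukey stage is
skippable (`include_tukey=False`) because studentized-range quantiles
dominate runtime in calibration loops.

## Seeding

Every generator accepts a seed; sessions derive per-trial streams as
`SeedSequence(master, spawn_key=(trial, stream))`, so adding trials or
conditions never perturbs existing ones, and a run is reconstructible from
its manifest alone.

## Problem sizes

The shipped checks use 40 s AP and 120 s WASP records at 1 kHz; parameter
recovery runs a 3 × 3 grid of (amplitude, time constant) × 50 seeds at
amplitude-to-noise ratio 20; device contrasts use 100 matched trials for
SNR ordering and 6–10 trials per device × cage cell for the ANOVAs;
type-I-error calibration uses 1000 null simulations per test. The whole
suite completes in under a minute on one CPU.

## What the generator does not emulate

Real recordings include electrode drift and polarization artifacts,
electrode–tissue contact impedance changes, gate-current transients,
temperature and hydration effects, biological refractoriness, and
propagation (the simulator exposes distant-trap null results only as a
signal-presence choice, not as tissue physics). Passing the synthetic
benchmark therefore shows that the *analysis chain* is correct and that
the *phenomenological device model* reproduces the reported contrasts —
not that a physical OECT will achieve a specific SNR on a given plant.
Absolute template amplitudes (tens of mV) and OECT curve parameters are
plausible placeholders, as the quantitative axes of the original figures
are not available in text form; the noise susceptibilities are calibrated
to the reported SNR pair rather than derived from device physics.
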