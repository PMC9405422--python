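# Methods

## The recording circuit and its transfer function

A cell-attached pipette in current clamp sees the cell interior through the
membrane patch — resistance R_patch in parallel with capacitance C_patch —
while the pipette node is shunted to bath through the seal resistance
R_seal in parallel with the electrode capacitance C_elec.  The recorded
voltage is therefore the membrane potential through the complex divider
H(jω) = Z_seal/(Z_patch + Z_seal).  Writing K_R = R_seal/R_patch,
K_C = C_elec/C_patch and τ = R_patch·C_patch, the amplitude response is

    AR(f) = sqrt((2π K_R τ f)² + K_R²) / sqrt((2π (K_C+1) K_R τ f)² + (K_R+1)²),

a low-shelf running from the resistive divider R_seal/(R_seal+R_patch) at
DC down to the capacitive divider C_patch/(C_patch+C_elec) at high
frequency, with the transition governed by τ.  `circuit.amplitude_response`
implements the closed form and `circuit.complex_transfer` the divider; the
two are algebraically identical and the package treats their agreement
(≤1e-10 relative) as a standing correctness oracle, tested over random
parameter draws.

Units are fixed package-wide: mV, s, Hz, pA, GOhm, pF.  Note GOhm·pF = ms;
`PatchCircuitParams.tau` converts to seconds so no hidden ms/s factors
survive into the maths.

**Time-domain filtering.**  H(s) = K_R(1+sτ) / [(K_R+1) + s(K_C+1)K_Rτ] is
discretised by the bilinear transform at the trace sampling rate, which
preserves the DC gain exactly and the low-frequency response accurately;
the filter state is initialised at steady state on the first sample so
synthetic CA traces carry no start-up transient.  Frequencies approaching
the Nyquist rate suffer the usual bilinear warping; sinusoid attenuation is
accurate to <1% for f ≤ rate/20 (tested).  A constant
`patch_current_offset` can be added after filtering to represent active
currents across the patch: a single 100 pS channel at 90 mV driving force
passes 9 pA and depolarises a 1 GOhm patch by 9 mV
(`single_channel_depolarization`), which is why CA baselines can sit
depolarised relative to the divider prediction.

**Fitting.**  `fit_transfer` estimates R_seal, R_patch and C_patch by
nonlinear least squares on a measured AR(f) table with C_elec supplied and
held fixed — amplitude-only data identify only the ratio C_elec/C_patch, so
a free C_elec is degenerate.  Parameters are optimised in log space
(positivity for free, scales equalised across decades); residuals are in
linear AR with an optional relative-error (log) weighting flag.
Initialisation inverts the two closed-form limits: R_seal/R_patch from the
lowest-frequency point (with a 5 GOhm R_patch prior) and C_patch from the
highest-frequency point.  On noiseless tables the generating parameters are
recovered to machine-level accuracy; with 1% multiplicative noise the
recovery stays within 10% (100-repeat Monte-Carlo test).  Phase is not
fitted and no pipette-series-resistance model is included.

## Signal-analysis conventions

- **WC spikes**: contiguous excursions above resting + 40 mV; resting
  defaults to the trace median.  Onset by backward scan for the latest
  upward 10 mV/ms derivative crossing (flagged fallback to peak − 100 ms).
- **CA spikes and WC PSPs**: upward 1 mV/ms crossings of the smoothed
  derivative, with 2 ms (spikes) or 50 ms (PSPs) refractory grouping;
  PSP onsets use the 0.1 mV/ms rule; ±10 ms around detected spikes is
  blanked before PSP detection.
- **Amplitude**: extremum minus the mean of the 1–5 ms pre-onset window
  (signed).  On a baseline drifting at b mV/ms this definition is biased by
  b·(3 ms + onset-to-peak) — the tests assert the analytic value.
  **Half-duration**: width at half amplitude with sub-sample interpolation;
  a crossing only counts if the signal stays beyond it for 5 ms, otherwise
  slow decays get truncated by brief noise dips.
- **Derivative smoothing**: thresholds in mV/ms are meaningless on raw
  wide-band noise, so derivatives are taken on zero-phase Butterworth
  low-passed copies — 1 kHz for WC detection, 300 Hz for CA spike detection
  (CA excess noise is twice the WC level), and PSP onset/measurement on a
  100 Hz copy, which passes the slow PSP waveform essentially undistorted
  while putting the 0.1 mV/ms onset threshold far above the derivative
  noise floor.  Spikes are measured on raw samples (they are fast relative
  to any of these cutoffs).  All cutoffs are arguments with these defaults.
- **Pairing**: WC-detected events keep their onsets; the CA peak is
  searched up to a configurable lag after the WC peak (5 ms for spikes,
  50 ms recommended for PSPs, whose filtered peaks lag tens of ms), and the
  CA event is measured with the WC-derived onset.  Summaries report the
  per-event CA/WC amplitude-ratio median and IQR, a through-origin slope
  and Pearson r.
- **Evoked responses**: largest |deflection| within 200 ms post-stimulus on
  the averaged trace, minus the 200 ms pre-stimulus median; polarity labels
  use a ±0.3 mV isoelectric dead band (the noise floor of averaged traces;
  configurable, since "isoelectric" has no standard width).
- **Dominant frequency**: 1/(3 × half-width), treating the event half-width
  as one third of the period of the matched oscillation.
- **Network events**: 3 × SD of the quietest 100 s episode (10 s search
  stride; traces shorter than 100 s fall back to the quietest half and are
  flagged) of the 1–100 Hz band, signed with declared polarity — negative
  for GDPs in the CA3 pyramidal layer, positive for SWRs in CA1; excursions
  closer than 200 ms are merged; the reference time is the extremum.
  Membrane change per event is the extremum of a 50 Hz-low-passed CA trace
  inside the event window minus the median of the preceding second.
  Multi-unit activity: negative crossings of 3 SD in the 300–2,500 Hz band
  with 1 ms dead time (requires ≥10 kHz sampling).  A true 3 SD threshold
  on stationary Gaussian noise necessarily passes some tail excursions
  (Rice's formula gives ~14 Hz for the MUA band, ~0.3 Hz for slow field
  events on pure noise); in realistic recordings the quietest-episode SD
  includes background activity, which is what keeps false positives rare.
- **Bridge compensation** (offline): boundaries where |dV/dt| exceeds 30%
  of the ON-phase derivative peak, where the ON phase is the first
  large-derivative excursion; the subtracted rectangle's amplitude is the
  jump at the ON boundary estimated from 0.2 ms means just outside/inside
  it (the membrane charges on a ~15 ms time constant, so its contribution
  over 0.2 ms is negligible).  Second applications of LJP correction and
  bridge subtraction are rejected/flagged.
- **LJP**: corrected = recorded − LJP (a 16 mV junction potential makes a
  −65 mV reading −81 mV).  Nernst potentials use T = 30 °C by default
  (bath temperature 30–32 °C); the standard pair (−92, −39) for 4/30 mM
  internal chloride against 136.1 mM bath is reproduced to ≤1 mV, the
  −39 figure being sensitive to rounding (−39.5 at 30 °C).

## The synthetic-data generator

The generator exists to give every pipeline stage an input with exact
ground truth; it is deliberately phenomenological.

- **Membrane**: a single-compartment leaky integrator
  dV/dt = (E_drive − V)/τ_m + I·R/τ_m (exponential-Euler update, exact for
  piecewise-constant input), E_rest = −81.3 mV, R_input = 100 MOhm,
  C_m = 150 pF (τ_m = 15 ms).  High-potassium application ramps E_drive
  linearly over the first and last fifth of the application window.
- **Spikes** are biphasic template insertions at threshold crossings
  (−45 mV, 50 ms refractory), not conductance-generated: the analysis
  concerns waveform transfer, and templates make ground truth exact.  The
  Gaussian depolarising lobe has 1.39 ms half-width, putting the spike
  dominant frequency at the observed ~240 Hz; amplitude 100 mV with a
  shallow after-hyperpolarisation.
- **PSPs** are additive difference-of-exponential voltage events (Poisson,
  0.8 Hz; log-normal amplitudes, median 3 mV, σ = 0.3).  Rise τ = 1 ms and
  decay τ = 112 ms give a ~82 ms half-width — dominant frequency ≈ 4 Hz,
  matching the observed sPSP band — and median-amplitude rise slopes of
  ~3 mV/ms, i.e. a population actually detectable by the 1 mV/ms rule, as
  the measurement method presupposes.  GABA events scale with driving
  force, amplitude = 0.075·(E_GABA − Em) mV per mV; there is no conductance
  shunting.
- **Noise**: white Gaussian SDs are specified at the 50 kHz acquisition
  bandwidth (WC 0.3 mV) and scaled by sqrt(rate/50 kHz) at lower simulation
  rates, so the noise *density* — and detector behaviour after
  band-limiting — is rate-invariant.  The CA channel adds independent white
  noise at twice the WC level (the observed baseline-SD ratio) plus a
  two-state telegraph process (2 mV steps, 1 Hz switching) standing in for
  sporadic channel gating in the patch; telegraph steps do not scale with
  rate.  Over quiet segments the CA/WC SD ratio equals the configured
  factor.
- **Network sessions**: the LFP is 1/f ("pink") noise (SD 0.03 mV) plus
  Gaussian-windowed field deflections — GDPs negative, 0.5 mV, 111 ms
  half-width (≈3 Hz dominant frequency); SWRs positive, 0.4 mV, 48 ms
  (≈7 Hz) — with multi-unit spikes clustered around each peak over a 20 Hz
  background.  The membrane deflects by +16.3 mV (GDP) or ±1.5 mV (SWR)
  around the field peak, fires bursts at the peak when depolarising, and is
  recorded through the circuit filter.  Event times are Poisson thinned to
  a minimum separation of max(4 × half-width, 0.3 s): events closer than
  the detector's 200 ms merge gap would be indistinguishable by
  construction, and slice GDPs/SWRs recur at second-scale intervals.
  Amplitudes jitter by 10%.  There is no volume-conduction physics and no
  ripple-band (150–250 Hz) structure — the waveforms exist to exercise the
  detectors, not to model extracellular fields.
- **GABA experiments** average n_stim evoked sweeps per holding level; the
  per-stimulus amplitude carries 0.5 mV Gaussian noise, and the CA sweep is
  the filtered WC sweep, so its baseline sits at dc_transfer × Em — the
  seal-induced depolarising offset that biases native-CA-frame reversal
  estimates and that reframing against the WC membrane potential removes.

What passing tests show — and what they do not: the generator shares the
*structure* of the experiments (paired channels distorted by a known
circuit, SD-relative thresholds, driving-force-linear GABA responses), so
the tests demonstrate that the estimators recover known truth under
realistic noise.  They cannot validate the circuit model itself against
biology, conductance interactions between events, electrode drift, or
non-stationary noise, none of which the generator emulates.

## Problem sizes and determinism

Simulated sessions used by the tests and analysis scripts run at a 5 kHz
profile (the acquisition rate was 50 kHz; the rate-invariant noise model
makes detector behaviour match across profiles) with ~120 s sessions, five
seeds for pipeline-recovery statistics, 100 Monte-Carlo repeats for noisy
fit recovery and E_GABA recovery, and 1000 random draws for the
model-equivalence property.  MUA examples run at 30 kHz for the 2.5 kHz
corner.  All generators are deterministic functions of an integer seed;
pipeline runs embed the seed and a config hash in their JSON summaries.

## Known limitations

- The quietest-interval search uses a stride of duration/10 (100 s episodes:
  10 s), so it approximates rather than exactly minimises the window SD.
- E_GABA estimation assumes a linear amplitude–Em relation (no
  Goldman-type rectification), matching how such data are usually fitted.
- The CA spike onset comes from its own 1 mV/ms detection crossing: the WC
  10 mV/ms onset rule cannot fire on filtered CA spikes, whose peak slope
  is only a few mV/ms.
- `filter_trace` models only the passive divider plus a constant offset;
  cases where the CA baseline is *hyperpolarised* relative to WC (seen in
  real recordings) have no mechanistic model here beyond a negative offset.
- Half-duration depends on the amplitude convention (half of the
  1–5 ms-baseline amplitude); alternative baseline conventions would shift
  absolute widths, though not the CA-vs-WC direction.
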