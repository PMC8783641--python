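# Methods

This note documents the models and procedures implemented in `hippolfp`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Preprocessing

Recordings are assumed to arrive as channels × time arrays in microvolts
with a probe map (shank, depth index, vertical spacing, anatomical layer).
`lowpass_downsample` applies a zero-phase Butterworth low-pass at 40% of the
*output* sampling rate — 413.6 Hz when targeting the standard 1034 Hz
analysis rate — followed by rational polyphase resampling, which handles
non-integer rate ratios (32 000 → 1034 Hz reduces to 517/16000). The filter
is order 8 per direction: at that order the response at 500 Hz is below 5%
of the passband, whereas order 4 (a common default) leaves ~18% leakage at
the same cutoff. Zero-phase filtering is used everywhere in the package
because the downstream analyses (theta phase, phase-amplitude coupling)
cannot tolerate group delay.

Re-applying the anti-alias filter to an already-downsampled *band-limited*
signal changes its RMS by well under 0.1%; for white-noise input the
transition band inherently retains ~1% of power, so idempotence is a
property of LFP-like (1/f) spectra, not of arbitrary signals.

## Event detection

All detectors share one primitive: band-pass (zero-phase Butterworth,
order 4 per direction), analytic-signal magnitude (Hilbert), Gaussian
smoothing (σ = 4 ms for ripple/fast-ripple bands, 10 ms for the slower
SPW/IED bands), standardized by the mean and SD over the session's
immobility samples. Immobility means speed < 1.5 cm/s sustained > 20 s with
theta/delta power ratio below 2 (the ratio is computed from band-passed RMS
in sliding 1 s windows).

* **Ripples** (150–250 Hz, stratum pyramidale): envelope > 3 SD for ≥ 15 ms;
  boundaries extended outward to the 1 SD crossings; events separated by
  less than 40 ms merged. The merge pass is idempotent.
* **Sharp waves** (4–50 Hz, stratum radiatum): envelope > 2.5 SD with a
  supra-threshold span between 20 and 400 ms; the span itself is the event.
* **SWR pairing**: each ripple pairs with the sharp wave of maximal temporal
  overlap; unpaired events of either kind are discarded.
* **Bursts**: events chain when consecutive peak-to-peak gaps are ≤ 200 ms;
  chains of 1/2/3/>3 events are singlets/doublets/triplets/higher.
  Peak-to-peak chaining (rather than a fixed window per anchor event) makes
  triplets well-defined.
* **Fast ripples** (nominally 250–600 Hz): at the 1034 Hz analysis rate the
  band is truncated to (250, 0.95 × Nyquist ≈ 491 Hz) with a warning, since
  the nominal upper edge exceeds Nyquist; four criteria are applied per
  candidate — envelope > 5 SD, at least six band-passed peaks each > 5 SD of
  the baseline filtered signal, and peak raw-spectrum power above 200 Hz
  exceeding the 75–125 Hz reference band (artifact guard).
* **Interictal discharges** (60–80 Hz): both the filtered envelope and the
  raw wideband envelope must exceed 5 SD over the same candidate window.

Cycle counts per ripple are positive-going band-passed peaks exceeding 25%
of the event maximum (a guard against counting noise wiggles); because
boundaries sit at the 1 SD crossings, the count tracks the *measured*
duration × frequency rather than the nominal extent of an injected
waveform. Ripple peak frequency is the argmax over a 101-wavelet Morlet
bank spanning the ripple band at the event peak. The SPW-amplitude vs
ripple-power session correlation is Pearson's r on per-event pairs.

## Spectral analysis

The canonical decomposition is a bank of complex Morlet wavelets, linearly
spaced and endpoint-inclusive (100 wavelets over 2–100 Hz for relative
power; 65 over 20–150 Hz for cycle-by-cycle gamma). Each kernel has
n_cycles = 6 cycles per temporal standard deviation (σ_t = n_cycles/2πf), a
standard time/frequency trade-off; `n_cycles` is configurable. Two kernel
normalizations are exposed: `amplitude` (default; a pure cosine of amplitude
A returns magnitude A, so power reads in µV²) and `energy` (unit L2 norm;
the response to white noise is flat across centre frequencies). Relative
power is the time-averaged power per frequency expressed as percent of the
total (sums to 100 by construction); band summaries integrate bins whose
centres fall inside the band.

Theta epochs are intervals where the theta/delta ratio exceeds 2 while
speed exceeds 2 cm/s (above the 1.5 cm/s immobility cutoff), minimum
duration 1 s; the segmentation is fully automatic, with all thresholds
configurable. Laminar profiles report per-channel theta power and the
circular-mean analytic-phase difference against a reference channel,
degrees in (−180, 180].

## Theta cycles and phase

Cycles are anchored by zero crossings of the 6–10 Hz filtered trace:
between consecutive crossings the wide-band (1–40 Hz) trace contributes one
peak (theta positive) or one trough (theta negative); ties break to the
earlier sample. Phase is interpolated linearly peak → trough (0° → 180°)
and trough → next peak (180° → 360°), so peaks read 0°/360° and troughs
exactly 180° regardless of cycle asymmetry. Cycles overlapping an epoch
boundary are discarded rather than truncated; epochs shorter than one theta
period are skipped with a log entry.

The 16-bin gamma-by-phase profile z-scores each bank frequency's amplitude
across all in-cycle samples of the session (per-sample z-scoring; an
alternative would z-score cycle means, but per-sample keeps the occupancy
identity: the occupancy-weighted mean of the binned values is exactly 0 per
frequency). Gamma sub-bands are slow 25–55 Hz, mid 65–90 Hz, fast
100–150 Hz (the fast upper edge is the bank maximum).

## Current-source density

CSD is the discrete second spatial difference divided by the squared
inter-site distance (mm), computed per shank on contiguous depth runs only;
the first and last site of each run are excluded, and runs shorter than
three sites contribute nothing (so excluding a middle channel can silently
empty a shank — by design, since interpolating across a gap would fabricate
data). No spatial smoothing is applied. Units are input units per mm²
(µV/mm² for recordings in µV). Depth-linear potentials — the signature of
volume conduction — map to exactly zero, and the operator is linear to
machine precision.

## Modulation index

Phase comes from the analytic signal of the 6–12 Hz filtered phase-provider
channel; the analysis is restricted to theta epochs longer than 1.5 s.
Amplitude is evaluated in 5 Hz non-overlapping windows from 20 to 200 Hz
(capped at 0.95 × Nyquist with a warning when the rate demands it). The
phase axis uses N = 18 bins (the convention of entropy-based MI), separate
from the 16-bin profile; both are configurable. MI = (log N − H)/log N of
the normalized phase-binned mean amplitude; each window also reports the
circular-mean preferred phase.

**Amplitude extraction is wavelet-based by design.** A 5 Hz-wide band-pass
filter cannot follow amplitude modulation at theta frequency: for any
band-limited process, the modulation sidebands sit ±6–12 Hz from the
carrier, outside a 5 Hz window, so a filter-Hilbert estimate returns a flat
envelope and MI ≈ 0 at any true coupling strength (we verified this
directly; the binned amplitude means are flat to within sampling error).
Morlet wavelets have bandwidth ∝ f/n_cycles (≈ 13 Hz at 80 Hz), which
retains the sidebands; the 5 Hz windows therefore act as *reporting*
windows: two wavelet centres per window, amplitudes averaged. The
filter-Hilbert variant is kept as `amp_method="filter"` and a test
documents the two orders of magnitude it loses against the wavelet route.

## Synthetic laminar sessions

The generator is the package's ground-truth instrument. One session
comprises:

* a speed trace (50 frames/s) of alternating immobility/locomotion bouts
  (defaults 60 s/60 s, 0.5 and 8 cm/s with small Gaussian jitter);
* laminar theta (8 Hz) with per-layer amplitude and phase offset — defaults
  place the power maximum and the ~180° phase reversal in stratum
  lacunosum-moleculare — gated on during locomotion (×0.2 at rest) with a
  0.25 s smoothed transition, plus a constant 2.5 Hz delta component so the
  theta/delta ratio segments brain state correctly;
* theta-phase-coupled gamma per layer with envelope
  amp × (1 + depth·cos(θ − φ_pref)), carried by band-limited Gaussian noise.
  A noise carrier is essential: a pure tone amplitude-modulated at theta
  places all modulation in ±8 Hz sidebands and is invisible to sub-band
  amplitude estimators, whereas broadband "bursty" gamma — the
  physiological reality — is not. (`synthesize_coupled_oscillation` defaults
  to the tone carrier, whose envelope is analytically checkable.)
* 1/f-shaped Gaussian noise (default exponent 1.0, 15 µV) plus white noise
  (3 µV) per channel;
* Poisson event trains during immobility — SWRs (Hann ripple burst in
  pyramidale + inverted Hann sharp wave in radiatum), optional interictal
  discharges (windowed 70 Hz transient) and fast ripples (flat-topped Tukey
  300 Hz burst, 10 cycles, so most oscillation peaks reach full amplitude) —
  placed uniformly within bouts with ≥ 250 ms separation. Doublets/triplets
  are injected only on explicit request (`BurstSpec`), keeping Poisson
  singlet labels unambiguous.

Event amplitudes are specified in baseline-SD units and made *operational*:
the SD unit is the immobility baseline of the finished session (events
included), obtained by a three-pass fixed-point iteration of the injection
against its own baseline, and the local pre-injection envelope is added to
each event's target so the nominal SD level is a floor even under
destructive interference with the background. Without these steps the
events inflate the baseline SD roughly twofold and nominal 4–6 SD events
realize at 2–4 SD. Waveform attenuation through each detector's filter +
smoothing chain is measured on the isolated unit waveform and divided out.

What the generator does **not** emulate: spike contamination, non-sinusoidal
theta waveform asymmetry, state transitions other than the speed gate,
electrode drift or artifacts, inter-shank heterogeneity, and any biophysical
(compartmental/dipole) forward model. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it claims to measure,
not that it is robust to every pathology of real recordings.

## Group statistics and behavior

Session summaries collect SWR incidence, peak-power statistics, median
wavelet peak frequency, cycles/event, duration, singlet/doublet/triplet
percentages (which partition 100% when no chain exceeds three events), the
SPW–ripple correlation, and per-band relative power / MI. Group comparisons
are thin wrappers: Mann-Whitney U (two-sided) for scalar session fields, and
per-bin two-sample t tests with Holm-Sidak step-down correction for
phase-bin curves (the correction family is the set of bins; configurable).
The behavioral discrimination index is DI = (Tmo − Tuo)/(Tmo + Tuo) for
interaction times with the moved and unmoved object.

## Problem sizes used in the test suite

Detector validation uses one 600 s immobility-only session at 0.4 SWR/s
(~240 events); coupling validation uses 120 s coupled signals; the
cohort-direction experiment uses 20 replicates of two 8-session cohorts of
120 s each (control-like: ripple 6 SD, LM mid-gamma depth 0.6; case-like:
4.5 SD, depth 0.2), chosen so the full suite completes in a few minutes on
one CPU while keeping every effect size at its configured value.

## Known limitations

* The fast-ripple band is structurally truncated at the 1034 Hz analysis
  rate; genuine 500–600 Hz content requires analyzing at a higher rate.
* Theta-epoch segmentation is fully automatic; no interactive adjustment
  step is provided, so borderline epochs follow the ratio threshold exactly.
* The MI's low amplitude windows (20–30 Hz) overlap the wavelet bandwidth of
  the phase band itself; values there should be interpreted cautiously.
* Detected-event amplitude distributions depend on the baseline definition
  (all immobility samples of the session); sessions with very high event
  rates compress measured SD values.
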