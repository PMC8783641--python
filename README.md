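# hippolfp

Analysis of hippocampal laminar local-field-potential (LFP) recordings:
sharp-wave-ripple (SWR), fast-ripple and interictal-discharge detection,
Morlet wavelet time-frequency analysis, theta cycle-by-cycle gamma
modulation, current-source density (CSD), and the theta–gamma modulation
index — together with a seeded synthetic laminar-LFP generator that provides
ground truth, so every stage of the pipeline can be validated without any
external recording.

The package is aimed at systems-neuroscience workflows on multi-shank
silicon-probe recordings across the CA1–dentate axis (e.g. 4 shanks × 8
sites, 200 µm vertical spacing), analyzed at 1034 Hz after anti-alias
low-pass filtering at 40% of the output rate (413.6 Hz).

## The quantities at the core

**SWR detection.** During immobility (speed < 1.5 cm/s for > 20 s, low
theta/delta ratio), the stratum pyramidale LFP is band-passed 150–250 Hz and
reduced to a smoothed analytic-signal envelope standardized in baseline-SD
units. Ripples are envelope excursions > 3 SD lasting ≥ 15 ms, extended to
the 1 SD crossings, with events closer than 40 ms merged. Sharp waves are
4–50 Hz excursions > 2.5 SD lasting 20–400 ms in stratum radiatum. An SWR is
a ripple co-occurring with a sharp wave; SWRs whose peaks fall within 200 ms
chain into doublets/triplets.

**CSD.** The second spatial derivative along a shank removes
volume-conducted components:

    CSD(n, t) = [LFP(n−1, t) − 2·LFP(n, t) + LFP(n+1, t)] / d²

with `d` the inter-site distance in mm.

**Theta cycle-by-cycle analysis.** Cycles are anchored on zero crossings of
the 6–10 Hz filtered trace; extrema are localized on a 1–40 Hz filtered
trace and phase is linearly interpolated so peaks read 0°/360° and troughs
180°. Morlet amplitudes (65 wavelets, 20–150 Hz) are z-scored over all
in-cycle samples and averaged in 16 phase bins.

**Modulation index.** For phase in 6–12 Hz and amplitude in 5 Hz windows
from 20 to 200 Hz, the phase-binned amplitude distribution `p` over N = 18
bins gives

    MI = (log N − H(p)) / log N,   H(p) = −Σ pⱼ log pⱼ

which is 0 when amplitude is independent of phase and 1 when all amplitude
mass falls in one bin.

## Worked example

Simulate a 300 s laminar session (alternating 60 s immobility/locomotion
bouts, 0.4 SWR/s, theta-locked gamma in stratum lacunosum-moleculare) and
run the detectors and coupling analysis:

```python
import numpy as np
import hippolfp as h

cfg = h.SynthConfig(
    duration_s=300.0, sites_per_shank=5,
    layer_profiles=(h.LayerProfile("str_pyramidale", 50, 0),
                    h.LayerProfile("str_radiatum", 60, 60),
                    h.LayerProfile("str_LM", 100, 180),
                    h.LayerProfile("dg_moleculare", 80, 200),
                    h.LayerProfile("dg_granule", 60, 215)),
    speed_profile=h.SpeedProfile(immobility_s=60.0, locomotion_s=60.0),
    swr_rate_hz=0.4, seed=42)
rec, cmap, speed, gt = h.generate_session(cfg)

imm = h.nominal_immobility(cfg)
pyr = rec.channel("s0d0")
ripples = [h.ripple_features(r, pyr, rec.rate_hz)
           for r in h.detect_ripples(pyr, rec.rate_hz, imm)]
spws = h.detect_spws(rec.channel("s0d1"), rec.rate_hz, imm)
swrs = h.pair_swr(ripples, spws)
print(f"injected SWRs: {len(gt.of_type('swr'))}, detected: {len(swrs)}")
print(f"incidence: {h.swr_incidence(swrs, imm):.3f} events/s")

epochs = h.detect_theta_epochs(pyr, rec.rate_hz, speed)
csd = h.compute_csd(rec, cmap)
com = h.modulation_index(pyr, csd.channel("s0d2"), rec.rate_hz, epochs)
best = np.argmax(com.mi)
print(f"max MI = {com.mi[best]:.4f} in the "
      f"{com.window_edges_hz[best,0]:.0f}-{com.window_edges_hz[best,1]:.0f} Hz window")
```

Output:

```
injected SWRs: 77, detected: 77
incidence: 0.428 events/s
max MI = 0.0095 in the 80-85 Hz window
```

All 77 injected events are recovered; the measured incidence (0.428/s)
matches the Poisson draw at the configured 0.4 events/s rate. The
comodulogram, computed on the CSD of the lacunosum-moleculare channel, peaks
inside the configured 65–90 Hz coupling band with its preferred phase at the
theta peak (configured 0°).

A command-line interface wraps the same stages
(`hippolfp simulate | preprocess | detect | spectra | coupling | report |
run`); `hippolfp run --out DIR` executes the whole pipeline on a simulated
session and writes every artifact (event tables, spectra, comodulogram,
summary JSON) next to the resolved config snapshot, so reruns with the same
seed are byte-identical.

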