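"""Synthetic laminar LFP sessions with known ground truth.

The generator emulates the statistical structure a hippocampal laminar
recording exposes to the analyses in this package:

* layer-dependent theta (6-10 Hz): amplitude and phase offset per channel,
  with the phase shift and power maximum placed in stratum
  lacunosum-moleculare by the default profiles;
* gamma sub-bands whose amplitude is locked to a preferred theta phase with a
  configurable modulation depth (envelope ``1 + depth*cos(phase - pref)``);
* Poisson trains of sharp-wave ripples — a Hann-windowed ripple-band burst in
  stratum pyramidale co-occurring with an inverted Hann sharp-wave bump in
  stratum radiatum — plus optional interictal discharges and fast ripples,
  all restricted to immobility bouts;
* 1/f-shaped Gaussian background noise plus white noise;
* a piecewise-constant speed trace (50 frames/s) alternating immobility and
  locomotion bouts, with theta and gamma gated on during locomotion.

Every injected event is listed in a ground-truth manifest, the oracle for
detector recall/precision and coupling-parameter recovery.  Identical config
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import hann, tukey

from .dsp import bandpass, smoothed_envelope, intervals_to_mask
from .errors import ConfigError, ParameterError
from .io import ChannelInfo, ChannelMap, LfpRecording, SpeedTrace

# Canonical depth profile along the CA1-dentate axis: (layer, theta amplitude
# in uV, theta phase offset in degrees).  Theta power peaks and the phase
# reverses (~180 deg) in stratum lacunosum-moleculare.
DEFAULT_LAYER_PROFILES = (
    ("str_oriens", 40.0, -20.0),
    ("str_pyramidale", 50.0, 0.0),
    ("str_radiatum", 60.0, 60.0),
    ("str_LM", 100.0, 180.0),
    ("dg_moleculare", 80.0, 200.0),
    ("dg_granule", 60.0, 215.0),
    ("hilus", 40.0, 225.0),
    ("unknown", 30.0, 225.0),
)


@dataclass(frozen=True)
class LayerProfile:
    layer: str
    theta_amp_uv: float
    theta_phase_deg: float


@dataclass(frozen=True)
class CouplingSpec:
    """Gamma band amplitude-locked to a theta phase in one layer."""
    band_hz: tuple
    pref_phase_deg: float
    depth: float
    amp_uv: float
    layer: str = "str_pyramidale"


@dataclass(frozen=True)
class SwrParams:
    ripple_freq_hz: float = 180.0
    ripple_amp_sd: float = 6.0       # peak ripple-band envelope, baseline-SD units
    ripple_dur_ms: float = 60.0
    spw_amp_sd: float = 4.0          # sharp-wave trough depth, baseline-SD units
    spw_dur_ms: float = 100.0


@dataclass(frozen=True)
class IedParams:
    freq_hz: float = 70.0
    amp_sd: float = 8.0
    dur_ms: float = 40.0


@dataclass(frozen=True)
class FastRippleParams:
    freq_hz: float = 300.0
    amp_sd: float = 7.0
    n_cycles: int = 10


@dataclass(frozen=True)
class NoiseSpec:
    pink_exponent: float = 1.0       # power spectrum ~ 1/f^exponent
    pink_sd_uv: float = 15.0
    white_sd_uv: float = 3.0


@dataclass(frozen=True)
class SpeedProfile:
    """Alternating immobility/locomotion bouts, immobility first."""
    immobility_s: float = 60.0
    locomotion_s: float = 60.0
    locomotion_speed_cm_s: float = 8.0
    immobility_speed_cm_s: float = 0.5
    jitter_cm_s: float = 0.15
    frame_rate_hz: float = 50.0


@dataclass(frozen=True)
class BurstSpec:
    """Explicitly requested SWR burst groups (doublets/triplets)."""
    n_members: int
    gap_ms: float = 120.0
    count: int = 1


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 600.0
    rate_hz: float = 1034.0
    n_shanks: int = 1
    sites_per_shank: int = 8
    site_spacing_mm: float = 0.2
    theta_freq_hz: float = 8.0
    delta_amp_uv: float = 20.0
    immobility_theta_factor: float = 0.2   # theta amplitude scale at rest
    layer_profiles: tuple = ()
    coupling_specs: tuple = (
        CouplingSpec((25.0, 55.0), 180.0, 0.4, 8.0, "str_radiatum"),
        CouplingSpec((65.0, 90.0), 0.0, 0.6, 6.0, "str_LM"),
        CouplingSpec((100.0, 150.0), 180.0, 0.5, 4.0, "str_pyramidale"),
    )
    swr_rate_hz: float = 0.4
    swr_params: SwrParams = field(default_factory=SwrParams)
    burst_specs: tuple = ()
    ied_rate_hz: float = 0.0
    ied_params: IedParams = field(default_factory=IedParams)
    fast_ripple_rate_hz: float = 0.0
    fast_ripple_params: FastRippleParams = field(default_factory=FastRippleParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    speed_profile: SpeedProfile = field(default_factory=SpeedProfile)
    seed: int = 0

    def __post_init__(self):
        if not self.layer_profiles:
            profs = tuple(LayerProfile(*p)
                          for p in DEFAULT_LAYER_PROFILES[: self.sites_per_shank])
            object.__setattr__(self, "layer_profiles", profs)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.n_shanks < 1 or self.sites_per_shank < 1:
            raise ConfigError("n_shanks and sites_per_shank must be >= 1")
        if self.site_spacing_mm <= 0:
            raise ConfigError("site_spacing_mm must be positive")
        if len(self.layer_profiles) != self.sites_per_shank:
            raise ConfigError(
                f"layer_profiles has {len(self.layer_profiles)} entries for "
                f"{self.sites_per_shank} sites per shank")
        highest = self.theta_freq_hz
        for spec in self.coupling_specs:
            if not 0.0 <= spec.depth <= 1.0:
                raise ConfigError(f"coupling depth {spec.depth} outside [0, 1]")
            highest = max(highest, spec.band_hz[1])
        if self.swr_rate_hz > 0:
            highest = max(highest, self.swr_params.ripple_freq_hz)
        if self.fast_ripple_rate_hz > 0:
            highest = max(highest, self.fast_ripple_params.freq_hz)
        if self.rate_hz <= 2.0 * highest:
            raise ConfigError(
                f"rate_hz ({self.rate_hz}) must exceed twice the highest "
                f"synthesized frequency ({highest})")
        for name in ("swr_rate_hz", "ied_rate_hz", "fast_ripple_rate_hz"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.n_shanks * self.sites_per_shank


EVENT_TYPES = ("swr", "ied", "fast_ripple")

GT_COLUMNS = ("type", "start_s", "end_s", "peak_s", "channel",
              "amplitude_sd", "freq_hz", "burst_id")


@dataclass(frozen=True)
class GroundTruthEvents:
    """Manifest of injected events and coupling, the analysis oracle."""
    events: pd.DataFrame
    coupling: pd.DataFrame
    duration_s: float

    def __post_init__(self):
        ev = self.events
        if len(ev):
            if not set(ev["type"]).issubset(EVENT_TYPES):
                raise ConfigError(f"event types must be in {EVENT_TYPES}")
            if not (ev["start_s"] < ev["end_s"]).all():
                raise ConfigError("event start must precede end")
            if (ev["start_s"] < 0).any() or (ev["end_s"] > self.duration_s).any():
                raise ConfigError("event times outside [0, duration_s]")

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["type"] == kind].reset_index(drop=True)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(directory / "ground_truth_events.tsv",
                           sep="\t", index=False)
        self.coupling.to_csv(directory / "ground_truth_coupling.tsv",
                             sep="\t", index=False)


# ---------------------------------------------------------------------------
# Primitive signal builders
# ---------------------------------------------------------------------------

def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ~ 1/f**exponent."""
    freqs = np.fft.rfftfreq(n)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    with np.errstate(divide="ignore"):
        scale = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _noise_carrier(n: int, rate_hz: float, band: tuple,
                   rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with unit mean analytic-signal envelope.

    Unlike a pure tone, a stochastic carrier spreads its energy across the
    whole band, so amplitude modulation survives narrow sub-band filtering —
    the bursty character of physiological gamma that comodulogram analyses
    rely on.  (A tone amplitude-modulated at theta frequency carries the
    modulation only in sidebands at +-theta Hz, which a sub-band filter
    strips entirely.)
    """
    x = bandpass(rng.standard_normal(n), rate_hz, band)
    from scipy.signal import hilbert
    return x / np.abs(hilbert(x)).mean()


def synthesize_coupled_oscillation(theta_freq_hz: float, amp_band_hz: tuple,
                                   pref_phase_deg: float, depth: float,
                                   duration_s: float, rate_hz: float,
                                   seed: int = 0, theta_amp: float = 1.0,
                                   noise_sd: float = 0.0,
                                   carrier: str = "tone") -> np.ndarray:
    """Theta plus a phase-amplitude-coupled fast oscillation, single channel.

    The fast component's envelope is ``1 + depth * cos(theta_phase -
    pref_phase)``, the textbook coupled-signal construction for validating
    coupling estimators.  ``carrier='tone'`` uses a deterministic sinusoid at
    the band centre (analytically checkable envelope); ``carrier='noise'``
    uses band-limited Gaussian noise (physiologically bursty gamma whose
    modulation is visible to narrow sub-band amplitude filters).
    """
    if not 0.0 <= depth <= 1.0:
        raise ParameterError(f"depth {depth} outside [0, 1]")
    lo, hi = amp_band_hz
    if not 0 < lo < hi < rate_hz / 2.0:
        raise ParameterError(f"amplitude band {amp_band_hz} outside (0, Nyquist)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    theta_phase = 2.0 * np.pi * theta_freq_hz * t
    envelope = 1.0 + depth * np.cos(theta_phase - np.deg2rad(pref_phase_deg))
    if carrier == "tone":
        fast = np.cos(2.0 * np.pi * 0.5 * (lo + hi) * t + rng.uniform(0, 2 * np.pi))
    elif carrier == "noise":
        fast = _noise_carrier(n, rate_hz, amp_band_hz, rng)
    else:
        raise ParameterError(f"unknown carrier {carrier!r}")
    x = theta_amp * np.cos(theta_phase) + envelope * fast
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return x


def generate_laminar_theta(config: SynthConfig,
                           gate: np.ndarray | None = None) -> np.ndarray:
    """Per-channel theta components with the configured laminar amplitude and
    phase-offset profile; ``gate`` (per-sample, [0, 1]) scales amplitude
    between its immobility floor and the full locomotion value."""
    n = int(round(config.duration_s * config.rate_hz))
    t = np.arange(n) / config.rate_hz
    phase = 2.0 * np.pi * config.theta_freq_hz * t
    if gate is None:
        amp_t = np.ones(n)
    else:
        f = config.immobility_theta_factor
        amp_t = f + (1.0 - f) * np.asarray(gate)
    out = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        prof = config.layer_profiles[ch % config.sites_per_shank]
        out[ch] = prof.theta_amp_uv * amp_t * np.cos(phase - np.deg2rad(prof.theta_phase_deg))
    return out


# ---------------------------------------------------------------------------
# Event waveform injection
# ---------------------------------------------------------------------------

def _windowed_tone(rate_hz: float, t_peak_s: float, dur_s: float,
                   freq_hz: float, amp: float, n_total: int,
                   invert_bump: bool = False, window: str = "hann") -> tuple:
    """Windowed waveform centred on ``t_peak_s``; returns (i0, samples).

    ``window='tukey'`` gives a flat-topped envelope (25% taper) so most
    oscillation peaks reach full amplitude — the shape used for fast
    ripples, whose detection counts supra-threshold peaks.
    """
    n = int(round(dur_s * rate_hz))
    if n < 2:
        raise ParameterError("event duration shorter than two samples")
    i_peak = int(round(t_peak_s * rate_hz))
    i0 = i_peak - n // 2
    if i0 < 0 or i0 + n > n_total:
        raise ParameterError(
            f"event at {t_peak_s:.3f} s extends outside the signal")
    w = hann(n, sym=True) if window == "hann" else tukey(n, 0.25, sym=True)
    if invert_bump:
        return i0, -amp * w
    tt = (np.arange(n) - n // 2) / rate_hz
    return i0, amp * w * np.cos(2.0 * np.pi * freq_hz * tt)


def inject_swr(signal_pyr: np.ndarray, signal_rad: np.ndarray, rate_hz: float,
               time_s: float, *, ripple_freq_hz: float = 180.0,
               ripple_dur_ms: float = 60.0, ripple_amp_uv: float = 0.0,
               spw_dur_ms: float = 100.0, spw_amp_uv: float = 0.0) -> tuple:
    """Add one sharp-wave-ripple pair at ``time_s`` (the event peak).

    The pyramidale channel gains a Hann-windowed ripple-frequency burst; the
    radiatum channel gains a concurrent inverted Hann deflection.  Amplitudes
    are in microvolts; zero amplitude leaves the signal untouched.  Copies are
    returned; samples outside the event windows are bit-identical to the
    input.
    """
    pyr = np.array(signal_pyr, dtype=float)
    rad = np.array(signal_rad, dtype=float)
    if ripple_amp_uv != 0.0:
        i0, wave = _windowed_tone(rate_hz, time_s, ripple_dur_ms * 1e-3,
                                  ripple_freq_hz, ripple_amp_uv, pyr.size)
        pyr[i0:i0 + wave.size] += wave
    if spw_amp_uv != 0.0:
        i0, wave = _windowed_tone(rate_hz, time_s, spw_dur_ms * 1e-3, 0.0,
                                  spw_amp_uv, rad.size, invert_bump=True)
        rad[i0:i0 + wave.size] += wave
    return pyr, rad


def inject_transient(signal: np.ndarray, rate_hz: float, time_s: float,
                     freq_hz: float, dur_ms: float, amp_uv: float,
                     window: str = "hann") -> np.ndarray:
    """Add one windowed oscillatory transient (IED / fast-ripple shape)."""
    out = np.array(signal, dtype=float)
    if amp_uv != 0.0:
        i0, wave = _windowed_tone(rate_hz, time_s, dur_ms * 1e-3, freq_hz,
                                  amp_uv, out.size, window=window)
        out[i0:i0 + wave.size] += wave
    return out


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def nominal_bouts(config: SynthConfig) -> list:
    """(start_s, end_s, is_immobile) bouts of the speed profile, immobility
    first, truncated to the session duration."""
    sp = config.speed_profile
    bouts, t, immobile = [], 0.0, True
    while t < config.duration_s - 1e-9:
        dur = sp.immobility_s if immobile else sp.locomotion_s
        if dur > 0:
            end = min(t + dur, config.duration_s)
            bouts.append((t, end, immobile))
            t = end
        immobile = not immobile
        if sp.immobility_s <= 0 and sp.locomotion_s <= 0:
            raise ConfigError("speed_profile bouts have zero total duration")
    return bouts


def nominal_immobility(config: SynthConfig) -> list:
    """Immobility intervals (start_s, end_s) implied by the speed profile."""
    return [(s, e) for s, e, imm in nominal_bouts(config) if imm]


def make_channel_map(config: SynthConfig) -> ChannelMap:
    infos = []
    for shank in range(config.n_shanks):
        for depth in range(config.sites_per_shank):
            prof = config.layer_profiles[depth]
            infos.append(ChannelInfo(
                channel_id=f"s{shank}d{depth}", shank=shank, depth=depth,
                spacing_mm=config.site_spacing_mm, layer=prof.layer))
    return ChannelMap(tuple(infos))


def _speed_trace(config: SynthConfig, rng: np.random.Generator) -> SpeedTrace:
    sp = config.speed_profile
    n = int(round(config.duration_s * sp.frame_rate_hz))
    times = np.arange(n) / sp.frame_rate_hz
    speed = np.full(n, sp.immobility_speed_cm_s)
    for s, e, immobile in nominal_bouts(config):
        if not immobile:
            sel = (times >= s) & (times < e)
            speed[sel] = sp.locomotion_speed_cm_s
    speed = np.clip(speed + sp.jitter_cm_s * rng.standard_normal(n), 0.0, None)
    return SpeedTrace(times_s=times, speed_cm_s=speed,
                      frame_rate_hz=sp.frame_rate_hz)


def _locomotion_gate(config: SynthConfig, n: int) -> np.ndarray:
    """Per-LFP-sample locomotion gate in [0, 1], 0.25 s Gaussian-smoothed."""
    gate = np.zeros(n)
    loco = [(s, e) for s, e, imm in nominal_bouts(config) if not imm]
    if loco:
        gate[intervals_to_mask(loco, n, config.rate_hz)] = 1.0
        gate = gaussian_filter1d(gate, sigma=0.25 * config.rate_hz)
    return gate


def _env_baseline(x: np.ndarray, rate_hz: float, band: tuple, sigma_ms: float,
                  mask: np.ndarray) -> tuple:
    """Smoothed band envelope plus its baseline mean/SD over masked samples."""
    env = smoothed_envelope(bandpass(x, rate_hz, band), rate_hz, sigma_ms)
    return env, float(env[mask].mean()), float(env[mask].std())


def _local_background(env: np.ndarray, rate_hz: float, t_s: float,
                      dur_s: float) -> float:
    """Peak pre-injection envelope over the event window.

    Adding this to the target amplitude makes ``amplitude_sd`` a floor on the
    realized envelope: even under fully destructive interference with the
    ongoing band-limited background the event still reaches its nominal
    baseline-SD level.
    """
    i = int(round(t_s * rate_hz))
    half = max(1, int(round(dur_s * rate_hz / 2)))
    return float(env[max(0, i - half):i + half].max())


def _waveform_gain(rate_hz: float, dur_s: float, freq_hz: float,
                   band: tuple | None, sigma_ms: float,
                   invert_bump: bool = False, window: str = "hann") -> float:
    """Peak smoothed band-envelope of the unit-amplitude event waveform.

    Band-pass filtering and envelope smoothing attenuate the injected
    waveform; dividing the target amplitude by this gain makes the *measured*
    envelope peak land at the nominal baseline-SD level.
    """
    pad = int(round(rate_hz))
    n = int(round(dur_s * rate_hz)) + 2 * pad
    i0, wave = _windowed_tone(rate_hz, pad / rate_hz + dur_s / 2.0, dur_s,
                              freq_hz, 1.0, n, invert_bump=invert_bump,
                              window=window)
    x = np.zeros(n)
    x[i0:i0 + wave.size] = wave
    if band is not None:
        x = bandpass(x, rate_hz, band)
    return float(smoothed_envelope(x, rate_hz, sigma_ms).max())


def _place_events(rng: np.random.Generator, bouts: list, n_events: int,
                  half_width_s: float, occupied: list,
                  min_gap_s: float = 0.25, margin_s: float = 0.3,
                  max_tries: int = 2000) -> list:
    """Uniform placement inside immobility bouts, rejecting candidates whose
    window comes within ``min_gap_s`` of an already-placed event window."""
    usable = [(s + margin_s + half_width_s, e - margin_s - half_width_s)
              for s, e in bouts if e - s > 2 * (margin_s + half_width_s)]
    if not usable and n_events > 0:
        raise ConfigError("no immobility bout long enough to host events")
    weights = np.array([e - s for s, e in usable], dtype=float)
    weights /= weights.sum()
    placed = []
    for _ in range(n_events):
        for _ in range(max_tries):
            s, e = usable[rng.choice(len(usable), p=weights)]
            t = rng.uniform(s, e)
            lo, hi = t - half_width_s, t + half_width_s
            if all(lo - min_gap_s >= oe or hi + min_gap_s <= os
                   for os, oe in occupied):
                occupied.append((lo, hi))
                placed.append(t)
                break
        else:
            break  # session saturated; manifest stays consistent with injections
    return placed


def generate_session(config: SynthConfig):
    """Generate one synthetic laminar session.

    Returns ``(LfpRecording, ChannelMap, SpeedTrace, GroundTruthEvents)``.
    Identical config and seed produce bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.rate_hz
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate

    speed = _speed_trace(config, rng)
    gate = _locomotion_gate(config, n)

    # --- background: laminar theta + delta + coupled gamma + noise ---------
    samples = generate_laminar_theta(config, gate=gate)
    theta_phase = 2.0 * np.pi * config.theta_freq_hz * t
    delta = config.delta_amp_uv * np.cos(
        2.0 * np.pi * 2.5 * t + rng.uniform(0, 2 * np.pi))
    samples += delta[None, :]

    layer_of = [config.layer_profiles[i % config.sites_per_shank].layer
                for i in range(config.n_channels)]
    for spec in config.coupling_specs:
        if spec.amp_uv == 0.0:
            continue
        envelope = spec.amp_uv * (1.0 + spec.depth * np.cos(
            theta_phase - np.deg2rad(spec.pref_phase_deg))) * gate
        for ch in range(config.n_channels):
            if layer_of[ch] == spec.layer:
                samples[ch] += envelope * _noise_carrier(n, rate,
                                                         spec.band_hz, rng)

    for ch in range(config.n_channels):
        noise = config.noise.pink_sd_uv * pink_noise(n, config.noise.pink_exponent, rng)
        if config.noise.white_sd_uv > 0:
            noise = noise + config.noise.white_sd_uv * rng.standard_normal(n)
        samples[ch] += noise

    cmap = make_channel_map(config)

    # --- events -------------------------------------------------------------
    immobility = nominal_immobility(config)
    total_imm = sum(e - s for s, e in immobility)
    rows: list = []
    any_rate = (config.swr_rate_hz > 0 or config.ied_rate_hz > 0
                or config.fast_ripple_rate_hz > 0 or config.burst_specs)
    if any_rate and total_imm > 0:
        pyr_ids = [i for i, l in enumerate(layer_of) if l == "str_pyramidale"]
        rad_ids = [i for i, l in enumerate(layer_of) if l == "str_radiatum"]
        if not pyr_ids:
            raise ConfigError("event injection requires a str_pyramidale channel")
        pyr = pyr_ids[0]
        imm_mask = intervals_to_mask(immobility, n, rate)

        occupied: list = []
        sw = config.swr_params
        swr_half = max(sw.ripple_dur_ms, sw.spw_dur_ms) * 1e-3 / 2.0

        # Poisson singlet train + explicitly requested burst groups.
        swr_times = []
        if config.swr_rate_hz > 0:
            n_swr = rng.poisson(config.swr_rate_hz * total_imm)
            swr_times = [(tm, -1) for tm in _place_events(
                rng, immobility, n_swr, swr_half, occupied)]
        burst_id = 0
        for bspec in config.burst_specs:
            group_half = swr_half + (bspec.n_members - 1) * bspec.gap_ms * 1e-3 / 2.0
            anchors = _place_events(rng, immobility, bspec.count, group_half,
                                    occupied)
            for anchor in anchors:
                start = anchor - (bspec.n_members - 1) * bspec.gap_ms * 1e-3 / 2.0
                for k in range(bspec.n_members):
                    swr_times.append((start + k * bspec.gap_ms * 1e-3, burst_id))
                burst_id += 1

        ied_times, fr_times = [], []
        if config.ied_rate_hz > 0:
            n_ied = rng.poisson(config.ied_rate_hz * total_imm)
            ied_times = _place_events(rng, immobility, n_ied,
                                      config.ied_params.dur_ms * 1e-3 / 2.0,
                                      occupied)
        if config.fast_ripple_rate_hz > 0:
            fr = config.fast_ripple_params
            n_fr = rng.poisson(config.fast_ripple_rate_hz * total_imm)
            fr_times = _place_events(rng, immobility, n_fr,
                                     fr.n_cycles / fr.freq_hz / 2.0, occupied)

        # Baseline-SD -> microvolt conversion.  The operational SD unit is
        # the session baseline measured *with* the events present (that is
        # what a detector standardizes against), and the events themselves
        # inflate it; a short fixed-point iteration injects against the
        # previous pass's baseline until the realized levels are expressed in
        # post-injection units.  Local pre-injection background is added so
        # amplitude_sd is a floor even under destructive interference.
        nyq = rate / 2.0
        swr_times = sorted(swr_times)
        ied_times = sorted(ied_times)
        fr_times = sorted(fr_times)
        ie = config.ied_params
        fr = config.fast_ripple_params
        fr_band = (250.0, min(600.0, 0.95 * nyq))
        fr_dur_ms = fr.n_cycles / fr.freq_hz * 1e3
        if swr_times and not rad_ids:
            raise ConfigError("SWR injection requires a str_radiatum channel")
        rad = rad_ids[0] if rad_ids else pyr

        clean_pyr = samples[pyr].copy()
        clean_rad = samples[rad].copy()
        g_rip = _waveform_gain(rate, sw.ripple_dur_ms * 1e-3,
                               sw.ripple_freq_hz, (150.0, 250.0), 4.0)
        g_spw = _waveform_gain(rate, sw.spw_dur_ms * 1e-3, 0.0,
                               (4.0, 50.0), 10.0, invert_bump=True)
        g_ied_band = _waveform_gain(rate, ie.dur_ms * 1e-3, ie.freq_hz,
                                    (60.0, 80.0), 10.0)
        g_ied_raw = _waveform_gain(rate, ie.dur_ms * 1e-3, ie.freq_hz,
                                   None, 10.0)
        g_fr = _waveform_gain(rate, fr_dur_ms * 1e-3, fr.freq_hz, fr_band, 4.0,
                              window="tukey")
        env_r0, _, _ = _env_baseline(clean_pyr, rate, (150.0, 250.0), 4.0, imm_mask)
        env_s0, _, _ = _env_baseline(clean_rad, rate, (4.0, 50.0), 10.0, imm_mask)

        cur_pyr, cur_rad = clean_pyr, clean_rad
        for _ in range(3):
            _, mu_r, sd_r = _env_baseline(cur_pyr, rate, (150.0, 250.0), 4.0, imm_mask)
            _, mu_s, sd_s = _env_baseline(cur_rad, rate, (4.0, 50.0), 10.0, imm_mask)
            new_pyr, new_rad = clean_pyr.copy(), clean_rad.copy()
            for tm, _bid in swr_times:
                rip_uv = (mu_r + sw.ripple_amp_sd * sd_r + _local_background(
                    env_r0, rate, tm, sw.ripple_dur_ms * 1e-3)) / g_rip
                spw_uv = (mu_s + sw.spw_amp_sd * sd_s + _local_background(
                    env_s0, rate, tm, sw.spw_dur_ms * 1e-3)) / g_spw
                new_pyr, new_rad = inject_swr(
                    new_pyr, new_rad, rate, tm,
                    ripple_freq_hz=sw.ripple_freq_hz,
                    ripple_dur_ms=sw.ripple_dur_ms, ripple_amp_uv=rip_uv,
                    spw_dur_ms=sw.spw_dur_ms, spw_amp_uv=spw_uv)
            if ied_times:
                env_b, mu_b, sd_b = _env_baseline(cur_pyr, rate, (60.0, 80.0),
                                                  10.0, imm_mask)
                raw_env = smoothed_envelope(cur_pyr, rate, 10.0)
                mu_raw = float(raw_env[imm_mask].mean())
                sd_raw = float(raw_env[imm_mask].std())
                env_b0, _, _ = _env_baseline(clean_pyr, rate, (60.0, 80.0),
                                             10.0, imm_mask)
                raw_env0 = smoothed_envelope(clean_pyr, rate, 10.0)
                for tm in ied_times:
                    dur_s = ie.dur_ms * 1e-3
                    amp = max(
                        (mu_b + ie.amp_sd * sd_b
                         + _local_background(env_b0, rate, tm, dur_s)) / g_ied_band,
                        (mu_raw + ie.amp_sd * sd_raw
                         + _local_background(raw_env0, rate, tm, dur_s)) / g_ied_raw)
                    new_pyr = inject_transient(new_pyr, rate, tm, ie.freq_hz,
                                               ie.dur_ms, amp)
            if fr_times:
                env_f0, _, _ = _env_baseline(clean_pyr, rate, fr_band, 4.0,
                                             imm_mask)
                _, mu_f, sd_f = _env_baseline(cur_pyr, rate, fr_band, 4.0,
                                              imm_mask)
                filt_sd = float(bandpass(cur_pyr, rate, fr_band)[imm_mask].std())
                for tm in fr_times:
                    # second term: band-passed peaks must clear amp_sd x the
                    # baseline filtered-signal SD (per-peak criterion)
                    amp = max(
                        (mu_f + fr.amp_sd * sd_f + _local_background(
                            env_f0, rate, tm, fr_dur_ms * 1e-3)) / g_fr,
                        1.2 * fr.amp_sd * filt_sd)
                    new_pyr = inject_transient(new_pyr, rate, tm, fr.freq_hz,
                                               fr_dur_ms, amp, window="tukey")
            cur_pyr, cur_rad = new_pyr, new_rad
        samples[pyr] = cur_pyr
        if rad != pyr:
            samples[rad] = cur_rad

        for tm, bid in swr_times:
            rows.append(("swr", tm - swr_half, tm + swr_half, tm,
                         cmap.channels[pyr].channel_id,
                         sw.ripple_amp_sd, sw.ripple_freq_hz, bid))
        for tm in ied_times:
            half = ie.dur_ms * 1e-3 / 2.0
            rows.append(("ied", tm - half, tm + half, tm,
                         cmap.channels[pyr].channel_id, ie.amp_sd,
                         ie.freq_hz, -1))
        for tm in fr_times:
            half = fr_dur_ms * 1e-3 / 2.0
            rows.append(("fast_ripple", tm - half, tm + half, tm,
                         cmap.channels[pyr].channel_id, fr.amp_sd,
                         fr.freq_hz, -1))

    events = pd.DataFrame(rows, columns=GT_COLUMNS).sort_values(
        "peak_s", kind="stable").reset_index(drop=True)
    coupling = pd.DataFrame(
        [{"band_low_hz": s.band_hz[0], "band_high_hz": s.band_hz[1],
          "pref_phase_deg": s.pref_phase_deg, "depth": s.depth,
          "layer": s.layer} for s in config.coupling_specs])
    gt = GroundTruthEvents(events=events, coupling=coupling,
                           duration_s=config.duration_s)

    rec = LfpRecording(samples=samples, rate_hz=rate,
                       channel_ids=cmap.channel_ids)
    return rec, cmap, speed, gt
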