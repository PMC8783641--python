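"""Sharp-wave-ripple, fast-ripple, and interictal-discharge detection.

Detection is restricted to immobility periods (speed < 1.5 cm/s for more than
20 s with low theta).  A band-limited signal is reduced to a smoothed
analytic-signal envelope, standardized to baseline-SD units where the
baseline is the concatenation of the session's immobility samples; events are
threshold crossings with duration and merge rules:

* ripples: 150-250 Hz, envelope > 3 SD for >= 15 ms, boundaries extended to
  the 1 SD crossings, events closer than 40 ms merged;
* sharp waves: 4-50 Hz, > 2.5 SD with supra-threshold span 20-400 ms;
* an SWR is a ripple (stratum pyramidale) overlapping a sharp wave (stratum
  radiatum); bursts are chains of SWRs with peak-to-peak gaps <= 200 ms;
* fast ripples: 250-600 Hz (truncated below Nyquist when needed), > 5 SD,
  at least six peaks each > 5 SD, and supra-200 Hz spectral peak dominating
  the 75-125 Hz range;
* IEDs: 60-80 Hz filtered envelope > 5 SD and raw envelope > 5 SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .dsp import (bandpass, find_runs, intervals_to_mask, smoothed_envelope,
                  theta_delta_ratio)
from .errors import InsufficientDataError, ParameterError
from .io import SpeedTrace

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    ripple_band: tuple = (150.0, 250.0)
    ripple_thresh_sd: float = 3.0
    ripple_min_ms: float = 15.0
    boundary_sd: float = 1.0
    merge_gap_ms: float = 40.0
    ripple_smooth_ms: float = 4.0

    spw_band: tuple = (4.0, 50.0)
    spw_thresh_sd: float = 2.5
    spw_min_ms: float = 20.0
    spw_max_ms: float = 400.0
    spw_smooth_ms: float = 10.0

    burst_window_ms: float = 200.0

    fr_band: tuple = (250.0, 600.0)
    fr_thresh_sd: float = 5.0
    fr_min_peaks: int = 6
    fr_peak_sd: float = 5.0
    fr_ref_band: tuple = (75.0, 125.0)
    fr_smooth_ms: float = 4.0

    ied_band: tuple = (60.0, 80.0)
    ied_filt_sd: float = 5.0
    ied_raw_sd: float = 5.0
    ied_smooth_ms: float = 10.0

    immobility_speed_cm_s: float = 1.5
    immobility_min_s: float = 20.0
    low_theta_ratio: float = 2.0

    def __post_init__(self):
        for name in ("ripple_band", "spw_band", "fr_band", "fr_ref_band", "ied_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ParameterError(f"{name} must be ordered low < high")
        for name in ("ripple_thresh_sd", "spw_thresh_sd", "fr_thresh_sd",
                     "ied_filt_sd", "ied_raw_sd", "ripple_min_ms", "spw_min_ms"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class ImmobilityPeriod:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    peak_power_sd: float
    peak_freq_hz: float = np.nan
    n_cycles: int = -1

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1e3


@dataclass(frozen=True)
class SpwEvent:
    start_s: float
    end_s: float
    amplitude_sd: float

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1e3


@dataclass(frozen=True)
class SwrEvent:
    ripple: RippleEvent
    spw: SpwEvent

    @property
    def peak_s(self) -> float:
        return self.ripple.peak_s


BURST_KINDS = {1: "singlet", 2: "doublet", 3: "triplet"}


@dataclass(frozen=True)
class BurstGroup:
    members: tuple

    @property
    def kind(self) -> str:
        return BURST_KINDS.get(len(self.members), "higher")


@dataclass(frozen=True)
class FastRippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    peak_amplitude_sd: float
    n_peaks: int


@dataclass(frozen=True)
class IedEvent:
    start_s: float
    end_s: float
    peak_s: float
    peak_amplitude_sd: float


# ---------------------------------------------------------------------------
# Immobility segmentation
# ---------------------------------------------------------------------------

def find_immobility_periods(speed: SpeedTrace, theta_ratio: np.ndarray,
                            params: DetectionParams) -> list:
    """Maximal intervals with speed below threshold and low theta/delta ratio,
    each at least ``immobility_min_s`` long.

    ``theta_ratio`` must be sampled on the speed-trace time grid.
    """
    if speed.times_s.size == 0:
        raise InsufficientDataError("empty speed trace")
    ratio = np.asarray(theta_ratio, dtype=float)
    if ratio.shape != speed.times_s.shape:
        raise ParameterError("theta_ratio must align with the speed trace")
    mask = (speed.speed_cm_s < params.immobility_speed_cm_s) & \
           (ratio < params.low_theta_ratio)
    dt = 1.0 / speed.frame_rate_hz
    periods = []
    for i0, i1 in find_runs(mask):
        start = speed.times_s[i0]
        end = speed.times_s[i1 - 1] + dt
        if end - start >= params.immobility_min_s:
            periods.append(ImmobilityPeriod(start, end))
    return periods


def immobility_theta_ratio(lfp: np.ndarray, rate_hz: float,
                           speed: SpeedTrace) -> np.ndarray:
    """Theta/delta ratio of an LFP channel sampled at the speed-trace times."""
    ratio = theta_delta_ratio(lfp, rate_hz)
    t_lfp = np.arange(lfp.size) / rate_hz
    return np.interp(speed.times_s, t_lfp, ratio)


# ---------------------------------------------------------------------------
# Envelope standardization
# ---------------------------------------------------------------------------

def envelope_sd(x: np.ndarray, rate_hz: float, band: tuple, baseline_periods,
                smooth_sigma_ms: float = 4.0) -> tuple:
    """Band-pass, envelope, and standardize to baseline-SD units.

    Returns ``(filtered, envelope_z)``.  The envelope is the Gaussian-smoothed
    magnitude of the analytic signal; its mean and SD over the concatenated
    ``baseline_periods`` define the zero and the SD unit.
    """
    if not baseline_periods:
        raise ParameterError("baseline_periods must be non-empty")
    filtered = bandpass(x, rate_hz, band)
    env = smoothed_envelope(filtered, rate_hz, smooth_sigma_ms)
    mask = intervals_to_mask(baseline_periods, x.size, rate_hz)
    if not mask.any():
        raise ParameterError("baseline periods cover no samples")
    mu, sd = env[mask].mean(), env[mask].std()
    if sd == 0:
        raise InsufficientDataError("zero baseline variance in envelope")
    return filtered, (env - mu) / sd


def _interval_indices(periods, n: int, rate_hz: float) -> list:
    out = []
    for p in periods:
        s = p.start_s if hasattr(p, "start_s") else p[0]
        e = p.end_s if hasattr(p, "end_s") else p[1]
        i0 = max(0, int(np.ceil(s * rate_hz)))
        i1 = min(n, int(np.ceil(e * rate_hz)))
        if i1 > i0:
            out.append((i0, i1))
    return out


def _threshold_events(env_z: np.ndarray, rate_hz: float, periods: list,
                      thresh: float, min_ms: float,
                      boundary: float | None = None,
                      merge_gap_ms: float = 0.0,
                      max_ms: float | None = None) -> list:
    """Core thresholding shared by the detectors: within each period find
    supra-``thresh`` runs of duration >= ``min_ms`` (and <= ``max_ms`` when
    given), optionally extend each to the surrounding ``boundary`` crossings,
    then merge events separated by less than ``merge_gap_ms``.  Returns index
    intervals [i0, i1)."""
    min_n = int(round(min_ms * 1e-3 * rate_hz))
    events = []
    for p0, p1 in _interval_indices(periods, env_z.size, rate_hz):
        seg = env_z[p0:p1]
        for r0, r1 in find_runs(seg >= thresh):
            if r1 - r0 < min_n:
                continue
            if max_ms is not None and (r1 - r0) / rate_hz * 1e3 > max_ms:
                continue
            i0, i1 = r0, r1
            if boundary is not None:
                while i0 > 0 and seg[i0 - 1] >= boundary:
                    i0 -= 1
                while i1 < seg.size and seg[i1] >= boundary:
                    i1 += 1
            events.append((p0 + i0, p0 + i1))
    events.sort()
    if merge_gap_ms > 0 and events:
        gap_n = merge_gap_ms * 1e-3 * rate_hz
        merged = [events[0]]
        for s, e in events[1:]:
            ps, pe = merged[-1]
            if s - pe < gap_n:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        events = merged
    return events


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_ripples(lfp_pyr: np.ndarray, rate_hz: float, immobility: list,
                   params: DetectionParams = DetectionParams()) -> list:
    """Ripple events on the stratum pyramidale channel.

    Envelope > ``ripple_thresh_sd`` for >= ``ripple_min_ms``; boundaries
    extended to the ``boundary_sd`` crossings; events with gaps below
    ``merge_gap_ms`` combined.  Only immobility periods are scanned and they
    also provide the baseline statistics.
    """
    if not immobility:
        log.warning("no immobility periods; returning no ripples")
        return []
    _, env = envelope_sd(lfp_pyr, rate_hz, params.ripple_band, immobility,
                         params.ripple_smooth_ms)
    out = []
    for i0, i1 in _threshold_events(env, rate_hz, immobility,
                                    params.ripple_thresh_sd,
                                    params.ripple_min_ms,
                                    boundary=params.boundary_sd,
                                    merge_gap_ms=params.merge_gap_ms):
        ipk = i0 + int(np.argmax(env[i0:i1]))
        out.append(RippleEvent(start_s=i0 / rate_hz, end_s=i1 / rate_hz,
                               peak_s=ipk / rate_hz,
                               peak_power_sd=float(env[ipk])))
    return out


def detect_spws(lfp_rad: np.ndarray, rate_hz: float, immobility: list,
                params: DetectionParams = DetectionParams()) -> list:
    """Sharp-wave events on the stratum radiatum channel: 4-50 Hz envelope
    > 2.5 SD with supra-threshold span between 20 and 400 ms."""
    if not immobility:
        log.warning("no immobility periods; returning no sharp waves")
        return []
    _, env = envelope_sd(lfp_rad, rate_hz, params.spw_band, immobility,
                         params.spw_smooth_ms)
    out = []
    for i0, i1 in _threshold_events(env, rate_hz, immobility,
                                    params.spw_thresh_sd, params.spw_min_ms,
                                    max_ms=params.spw_max_ms):
        out.append(SpwEvent(start_s=i0 / rate_hz, end_s=i1 / rate_hz,
                            amplitude_sd=float(env[i0:i1].max())))
    return out


def pair_swr(ripples: list, spws: list,
             params: DetectionParams = DetectionParams()) -> list:
    """One SWR per ripple that overlaps at least one sharp wave; ties go to
    the sharp wave with maximal temporal overlap.  Unpaired events drop."""
    out = []
    for rip in ripples:
        best, best_ov = None, 0.0
        for spw in spws:
            ov = min(rip.end_s, spw.end_s) - max(rip.start_s, spw.start_s)
            if ov > best_ov:
                best, best_ov = spw, ov
        if best is not None:
            out.append(SwrEvent(ripple=rip, spw=best))
    return out


def classify_bursts(swrs: list,
                    params: DetectionParams = DetectionParams()) -> list:
    """Chain events whose consecutive peak gaps are within the burst window;
    chains of 1/2/3/more are singlets/doublets/triplets/higher.  Every event
    lands in exactly one group."""
    events = sorted(swrs, key=lambda e: e.peak_s)
    window_s = params.burst_window_ms * 1e-3
    groups, current = [], []
    for ev in events:
        if current and ev.peak_s - current[-1].peak_s <= window_s:
            current.append(ev)
        else:
            if current:
                groups.append(BurstGroup(tuple(current)))
            current = [ev]
    if current:
        groups.append(BurstGroup(tuple(current)))
    return groups


def ripple_features(event: RippleEvent, lfp_pyr: np.ndarray, rate_hz: float,
                    params: DetectionParams = DetectionParams(),
                    n_freqs: int = 101) -> RippleEvent:
    """Fill wavelet peak frequency and cycle count for one ripple event.

    Peak frequency is the argmax over a Morlet bank spanning the ripple band
    at the event peak sample; cycles are positive-going band-passed peaks
    exceeding 25% of the event maximum (guards against noise wiggles).
    """
    from .spectral import make_bank, wavelet_transform  # local to avoid cycle

    i0 = int(round(event.start_s * rate_hz))
    i1 = int(round(event.end_s * rate_hz))
    if i0 < 0 or i1 > lfp_pyr.size or i1 <= i0:
        raise ParameterError("event lies outside the signal span")
    pad = int(round(0.1 * rate_hz))
    s0, s1 = max(0, i0 - pad), min(lfp_pyr.size, i1 + pad)
    bank = make_bank(params.ripple_band[0], params.ripple_band[1], n_freqs,
                     rate_hz=rate_hz)
    tf = wavelet_transform(lfp_pyr[s0:s1], bank)
    ipk = int(round(event.peak_s * rate_hz)) - s0
    peak_freq = float(bank.center_freqs_hz[int(np.argmax(tf.power[:, ipk]))])

    seg = bandpass(lfp_pyr, rate_hz, params.ripple_band)[i0:i1]
    height = 0.25 * np.abs(seg).max()
    peaks, _ = sps.find_peaks(seg, height=height)
    return replace(event, peak_freq_hz=peak_freq, n_cycles=int(peaks.size))


def detect_fast_ripples(lfp_pyr: np.ndarray, rate_hz: float, immobility: list,
                        params: DetectionParams = DetectionParams(),
                        allow_band_truncation: bool = True) -> list:
    """Fast-ripple (pathological >250 Hz) events.

    Four criteria per candidate: envelope > ``fr_thresh_sd``; at least
    ``fr_min_peaks`` filtered-signal peaks each > ``fr_peak_sd`` (in units of
    the baseline filtered-signal SD); and the raw-segment spectral peak above
    200 Hz must dominate the 75-125 Hz reference band.  When the nominal band
    tops out above Nyquist it is truncated to 0.95 x Nyquist (with a warning)
    unless truncation is disallowed.
    """
    if not immobility:
        return []
    nyq = rate_hz / 2.0
    lo, hi = params.fr_band
    if hi >= nyq:
        if not allow_band_truncation:
            raise ParameterError(
                f"fast-ripple band {params.fr_band} exceeds Nyquist {nyq} Hz")
        hi = 0.95 * nyq
        warnings.warn(
            f"fast-ripple band truncated to ({lo}, {hi:.1f}) Hz below Nyquist",
            stacklevel=2)
    filtered, env = envelope_sd(lfp_pyr, rate_hz, (lo, hi), immobility,
                                params.fr_smooth_ms)
    mask = intervals_to_mask(immobility, lfp_pyr.size, rate_hz)
    filt_sd = filtered[mask].std()
    out = []
    for i0, i1 in _threshold_events(env, rate_hz, immobility,
                                    params.fr_thresh_sd, min_ms=1.0,
                                    boundary=params.boundary_sd):
        seg = filtered[i0:i1] / filt_sd
        peaks, _ = sps.find_peaks(seg, height=params.fr_peak_sd)
        enough_peaks = peaks.size >= params.fr_min_peaks
        # artifact check: spectral dominance of the fast band in the raw trace
        pad = int(round(0.02 * rate_hz))
        raw = lfp_pyr[max(0, i0 - pad):min(lfp_pyr.size, i1 + pad)]
        freqs, psd = sps.periodogram(raw, fs=rate_hz)
        fast = psd[(freqs > 200.0)].max(initial=0.0)
        ref = psd[(freqs >= params.fr_ref_band[0])
                  & (freqs <= params.fr_ref_band[1])].max(initial=0.0)
        dominant = fast > ref
        log.debug("fast-ripple candidate [%d:%d): peaks=%d (>=%d: %s), "
                  "spectral dominance: %s", i0, i1, peaks.size,
                  params.fr_min_peaks, enough_peaks, dominant)
        if enough_peaks and dominant:
            ipk = i0 + int(np.argmax(env[i0:i1]))
            out.append(FastRippleEvent(start_s=i0 / rate_hz, end_s=i1 / rate_hz,
                                       peak_s=ipk / rate_hz,
                                       peak_amplitude_sd=float(env[ipk]),
                                       n_peaks=int(peaks.size)))
    return out


def detect_ieds(lfp_pyr: np.ndarray, rate_hz: float, immobility: list,
                params: DetectionParams = DetectionParams()) -> list:
    """Interictal discharges: 60-80 Hz filtered envelope > 5 SD AND raw
    (wideband) envelope > 5 SD over the same candidate window."""
    if not immobility:
        return []
    _, env = envelope_sd(lfp_pyr, rate_hz, params.ied_band, immobility,
                         params.ied_smooth_ms)
    raw_env = smoothed_envelope(lfp_pyr, rate_hz, params.ied_smooth_ms)
    mask = intervals_to_mask(immobility, lfp_pyr.size, rate_hz)
    mu, sd = raw_env[mask].mean(), raw_env[mask].std()
    raw_z = (raw_env - mu) / sd
    out = []
    for i0, i1 in _threshold_events(env, rate_hz, immobility,
                                    params.ied_filt_sd, min_ms=1.0,
                                    boundary=params.boundary_sd):
        if raw_z[i0:i1].max() >= params.ied_raw_sd:
            ipk = i0 + int(np.argmax(env[i0:i1]))
            out.append(IedEvent(start_s=i0 / rate_hz, end_s=i1 / rate_hz,
                                peak_s=ipk / rate_hz,
                                peak_amplitude_sd=float(env[ipk])))
    return out


# ---------------------------------------------------------------------------
# Session features
# ---------------------------------------------------------------------------

def swr_incidence(swrs: list, immobility: list) -> float:
    """SWR count per second of immobility."""
    total = sum((p.end_s if hasattr(p, "end_s") else p[1])
                - (p.start_s if hasattr(p, "start_s") else p[0])
                for p in immobility)
    if total <= 0:
        raise InsufficientDataError("zero immobility time")
    return len(swrs) / total


def spw_ripple_correlation(swrs: list) -> float:
    """Pearson correlation between per-event sharp-wave amplitude and ripple
    peak power (both in baseline-SD units)."""
    if len(swrs) < 3:
        raise InsufficientDataError(
            f"need >= 3 events for a correlation, got {len(swrs)}")
    spw_amp = np.array([e.spw.amplitude_sd for e in swrs])
    rip_pow = np.array([e.ripple.peak_power_sd for e in swrs])
    return float(spstats.pearsonr(spw_amp, rip_pow).statistic)
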