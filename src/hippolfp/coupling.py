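"""Theta cycle extraction, current-source density, and theta-gamma coupling.

Theta cycles are anchored on the 6-10 Hz filtered signal's zero crossings;
the actual peak/trough samples are located on a wider 1-40 Hz filtered trace
and phase is linearly interpolated peak -> trough (0 -> 180 degrees) and
trough -> next peak (180 -> 360 degrees), so peaks read 0/360 and troughs
180 regardless of cycle asymmetry.

CSD is the discrete second spatial derivative along a shank,
``(LFP[n-1] - 2 LFP[n] + LFP[n+1]) / distance**2`` with distance in mm, which
removes volume-conducted (depth-linear) components exactly.

The modulation index MI = (log N - H) / log N measures how far the
phase-binned amplitude distribution departs from uniform (H is its Shannon
entropy over N phase bins): 0 for amplitude independent of phase, 1 when all
amplitude mass sits in a single bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .dsp import bandpass, intervals_to_mask
from .errors import InsufficientDataError, ParameterError
from .io import ChannelMap, LfpRecording
from .spectral import WaveletBank, wavelet_amplitude

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThetaCycle:
    peak_start_s: float
    trough_s: float
    peak_end_s: float
    start_idx: int
    trough_idx: int
    end_idx: int


@dataclass(frozen=True)
class PhaseBinProfile:
    """Mean z-scored amplitude per (frequency x theta-phase bin)."""
    bin_edges_deg: np.ndarray          # 17 edges over [0, 360]
    freqs_hz: np.ndarray
    values: np.ndarray                 # (n_freqs, 16)
    occupancy: np.ndarray              # samples per bin

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


@dataclass(frozen=True)
class CsdSignal:
    """Second-spatial-derivative signal on the interior channels of each
    contiguous depth run; units are (input units)/mm^2."""
    values: np.ndarray
    channel_ids: tuple
    rate_hz: float

    def channel(self, channel_id) -> np.ndarray:
        return self.values[self.channel_ids.index(str(channel_id))]


@dataclass(frozen=True)
class Comodulogram:
    phase_band_hz: tuple
    window_edges_hz: np.ndarray        # (n_windows, 2)
    mi: np.ndarray
    pref_phase_deg: np.ndarray
    n_phase_bins: int


@dataclass(frozen=True)
class MiParams:
    phase_band_hz: tuple = (6.0, 12.0)
    amp_min_hz: float = 20.0
    amp_max_hz: float = 200.0
    amp_step_hz: float = 5.0
    n_phase_bins: int = 18
    min_epoch_s: float = 1.5
    # Amplitude extraction: 'wavelet' averages Morlet amplitudes (n_cycles
    # wavelets, bandwidth ~ f/n_cycles) over centres inside each 5 Hz window,
    # so theta-rate amplitude modulation at gamma frequencies stays visible.
    # 'filter' (band-pass + Hilbert per window) is provided for comparison,
    # but a 5 Hz-wide filter cannot follow amplitude changes faster than its
    # own bandwidth and suppresses coupling at phase frequencies above ~2.5 Hz.
    amp_method: str = "wavelet"
    wavelet_cycles: float = 6.0


# ---------------------------------------------------------------------------
# Theta cycles
# ---------------------------------------------------------------------------

def extract_theta_cycles(lfp: np.ndarray, rate_hz: float, epochs,
                         wide_band: tuple = (1.0, 40.0),
                         theta_band: tuple = (6.0, 10.0)) -> tuple:
    """Cycle-by-cycle theta phase by linear interpolation between extrema.

    Returns ``(cycles, phase_deg)`` where ``phase_deg`` is a full-length
    array in [0, 360) inside cycles and NaN elsewhere.  Cycles overlapping an
    epoch boundary are discarded; epochs shorter than one theta period are
    skipped with a log entry.
    """
    wide = bandpass(lfp, rate_hz, wide_band)
    theta = bandpass(lfp, rate_hz, theta_band)

    # Alternating extrema anchored by theta zero crossings: between two
    # consecutive crossings the wide-band trace contributes one peak (theta
    # positive) or one trough (theta negative); ties break to the earlier
    # sample (np.argmax/argmin convention).
    sign = np.sign(theta)
    crossings = np.flatnonzero(np.diff(sign > 0)) + 1
    extrema = []  # (index, is_peak)
    bounds = np.concatenate(([0], crossings, [lfp.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        if theta[a:b].mean() > 0:
            extrema.append((a + int(np.argmax(wide[a:b])), True))
        else:
            extrema.append((a + int(np.argmin(wide[a:b])), False))

    min_period = rate_hz / theta_band[1]
    phase = np.full(lfp.size, np.nan)
    cycles = []
    for epoch in epochs:
        e0 = epoch.start_s if hasattr(epoch, "start_s") else epoch[0]
        e1 = epoch.end_s if hasattr(epoch, "end_s") else epoch[1]
        if (e1 - e0) * rate_hz < min_period:
            log.info("epoch [%.2f, %.2f] s shorter than one theta period; "
                     "skipped", e0, e1)
            continue
        i0, i1 = int(np.ceil(e0 * rate_hz)), int(np.floor(e1 * rate_hz))
        inside = [(i, pk) for i, pk in extrema if i0 <= i < i1]
        for k in range(len(inside) - 2):
            (p, is_p), (tr, is_t), (p2, is_p2) = inside[k:k + 3]
            if not (is_p and not is_t and is_p2):
                continue
            if tr <= p or p2 <= tr:
                continue
            idx = np.arange(p, p2)
            ph = np.where(idx <= tr,
                          180.0 * (idx - p) / (tr - p),
                          180.0 + 180.0 * (idx - tr) / (p2 - tr))
            phase[p:p2] = ph
            cycles.append(ThetaCycle(peak_start_s=p / rate_hz,
                                     trough_s=tr / rate_hz,
                                     peak_end_s=p2 / rate_hz,
                                     start_idx=p, trough_idx=tr, end_idx=p2))
    return cycles, phase


# ---------------------------------------------------------------------------
# Current source density
# ---------------------------------------------------------------------------

def csd_second_difference(profile: np.ndarray, spacing_mm: float) -> np.ndarray:
    """CSD of a (depths x time) block with uniform spacing: the interior
    second difference divided by spacing squared."""
    arr = np.atleast_2d(np.asarray(profile, dtype=float))
    if arr.shape[0] < 3:
        raise ParameterError("CSD needs at least 3 contiguous depths")
    return (arr[:-2] - 2.0 * arr[1:-1] + arr[2:]) / spacing_mm ** 2


def compute_csd(rec: LfpRecording, cmap: ChannelMap) -> CsdSignal:
    """CSD per shank over contiguous depth runs; the first and last depth of
    each run are excluded, so a run of d contiguous depths yields d - 2 CSD
    channels (runs shorter than 3 yield none).  Non-uniform spacing within a
    shank raises a parameter error."""
    cmap.check_against(rec)
    values, ids = [], []
    for shank, infos in cmap.by_shank().items():
        spacings = {c.spacing_mm for c in infos}
        if len(spacings) > 1:
            raise ParameterError(f"non-uniform spacing on shank {shank}: {spacings}")
        spacing = infos[0].spacing_mm
        run = [infos[0]]
        runs = []
        for c in infos[1:]:
            if c.depth == run[-1].depth + 1:
                run.append(c)
            else:
                runs.append(run)
                run = [c]
        runs.append(run)
        for run in runs:
            if len(run) < 3:
                continue
            block = np.stack([rec.channel(c.channel_id) for c in run])
            values.append(csd_second_difference(block, spacing))
            ids.extend(c.channel_id for c in run[1:-1])
    if values:
        stacked = np.concatenate(values, axis=0)
    else:
        stacked = np.empty((0, rec.n_samples))
    return CsdSignal(values=stacked, channel_ids=tuple(ids), rate_hz=rec.rate_hz)


# ---------------------------------------------------------------------------
# Gamma amplitude by theta phase
# ---------------------------------------------------------------------------

def gamma_by_theta_phase(signal: np.ndarray, phase_deg: np.ndarray,
                         bank: WaveletBank, n_bins: int = 16) -> PhaseBinProfile:
    """Mean z-scored wavelet amplitude per theta-phase bin.

    Amplitude at each bank frequency is z-scored across all in-cycle samples
    of the session, then averaged within ``n_bins`` phase bins over
    [0, 360) degrees.
    """
    in_cycle = np.isfinite(phase_deg)
    if not in_cycle.any():
        raise InsufficientDataError("no theta cycles to bin")
    amp = wavelet_amplitude(signal, bank)[:, in_cycle]
    mu = amp.mean(axis=1, keepdims=True)
    sd = amp.std(axis=1, keepdims=True)
    z = (amp - mu) / np.where(sd > 0, sd, 1.0)

    edges = np.linspace(0.0, 360.0, n_bins + 1)
    which = np.clip(np.digitize(phase_deg[in_cycle], edges) - 1, 0, n_bins - 1)
    occupancy = np.bincount(which, minlength=n_bins)
    values = np.zeros((amp.shape[0], n_bins))
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            values[:, b] = z[:, sel].mean(axis=1)
    return PhaseBinProfile(bin_edges_deg=edges, freqs_hz=bank.center_freqs_hz.copy(),
                           values=values, occupancy=occupancy)


def band_phase_modulation(profile: PhaseBinProfile, band: tuple) -> np.ndarray:
    """Phase-modulation curve of one gamma sub-band: the profile averaged
    over bank frequencies whose centres fall inside the band."""
    lo, hi = band
    sel = (profile.freqs_hz >= lo) & (profile.freqs_hz <= hi)
    if not sel.any():
        raise ParameterError(f"band {band} contains no bank frequencies")
    return profile.values[sel].mean(axis=0)


# ---------------------------------------------------------------------------
# Modulation index
# ---------------------------------------------------------------------------

def mi_from_distribution(p: np.ndarray) -> float:
    """MI of a (normalized) phase-binned amplitude distribution:
    (log N - H) / log N with H the Shannon entropy."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise InsufficientDataError("distribution has zero mass")
    p = p / total
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float((np.log(p.size) - entropy) / np.log(p.size))


def modulation_index(phase_signal: np.ndarray, amp_signal: np.ndarray,
                     rate_hz: float, epochs,
                     params: MiParams = MiParams()) -> Comodulogram:
    """Theta-gamma comodulogram via the entropy-based modulation index.

    Phase comes from the analytic signal of the 6-12 Hz filtered
    ``phase_signal``; amplitude from the analytic magnitude of
    ``amp_signal`` band-passed in 5 Hz non-overlapping windows from 20 to
    200 Hz.  Only epochs longer than ``min_epoch_s`` contribute.  Windows
    reaching Nyquist are capped at 0.95 x Nyquist with a warning.
    """
    spans = []
    for e in epochs:
        s = e.start_s if hasattr(e, "start_s") else e[0]
        t = e.end_s if hasattr(e, "end_s") else e[1]
        if t - s > params.min_epoch_s:
            spans.append((s, t))
    if not spans:
        raise InsufficientDataError(
            f"no epochs longer than {params.min_epoch_s} s")
    n = len(phase_signal)
    mask = intervals_to_mask(spans, n, rate_hz)

    phase = np.angle(sps.hilbert(bandpass(phase_signal, rate_hz,
                                          params.phase_band_hz)))[mask]
    edges_deg = np.linspace(-180.0, 180.0, params.n_phase_bins + 1)
    which = np.clip(np.digitize(np.degrees(phase), edges_deg) - 1,
                    0, params.n_phase_bins - 1)
    centers = np.deg2rad(0.5 * (edges_deg[:-1] + edges_deg[1:]))

    nyq = rate_hz / 2.0
    amp_max = params.amp_max_hz
    if amp_max >= 0.95 * nyq:
        amp_max = 0.95 * nyq
        warnings.warn(f"amplitude windows capped at {amp_max:.1f} Hz below "
                      f"Nyquist", stacklevel=2)
    lows = np.arange(params.amp_min_hz, amp_max, params.amp_step_hz)
    windows = np.array([(lo, min(lo + params.amp_step_hz, amp_max))
                        for lo in lows])

    if params.amp_method == "wavelet":
        from .spectral import WaveletBank  # centres: 2 per 5 Hz window
        quarter = params.amp_step_hz / 4.0
        centres = np.sort(np.concatenate([windows[:, 0] + quarter,
                                          windows[:, 1] - quarter]))
        bank = WaveletBank(center_freqs_hz=centres,
                           n_cycles=params.wavelet_cycles, rate_hz=rate_hz)
        def window_amp(lo, hi):
            sel = (centres >= lo) & (centres <= hi)
            amps = [np.abs(sps.fftconvolve(amp_signal, bank.kernel(f),
                                           mode="same"))[mask]
                    for f in centres[sel]]
            return np.mean(amps, axis=0)
    elif params.amp_method == "filter":
        def window_amp(lo, hi):
            return np.abs(sps.hilbert(bandpass(amp_signal, rate_hz,
                                               (lo, hi))))[mask]
    else:
        raise ParameterError(f"unknown amp_method {params.amp_method!r}")

    mi = np.empty(len(windows))
    pref = np.empty(len(windows))
    for i, (lo, hi) in enumerate(windows):
        amp = window_amp(lo, hi)
        sums = np.bincount(which, weights=amp, minlength=params.n_phase_bins)
        counts = np.bincount(which, minlength=params.n_phase_bins)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        mi[i] = mi_from_distribution(means)
        weights = means / means.sum()
        pref[i] = np.degrees(np.angle(np.sum(weights * np.exp(1j * centers))))
    return Comodulogram(phase_band_hz=params.phase_band_hz,
                        window_edges_hz=windows, mi=mi, pref_phase_deg=pref,
                        n_phase_bins=params.n_phase_bins)


def band_mi(com: Comodulogram, band: tuple) -> float:
    """Mean MI over amplitude windows fully inside ``band``."""
    sel = (com.window_edges_hz[:, 0] >= band[0]) & \
          (com.window_edges_hz[:, 1] <= band[1])
    if not sel.any():
        raise ParameterError(f"no amplitude windows inside {band}")
    return float(com.mi[sel].mean())
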