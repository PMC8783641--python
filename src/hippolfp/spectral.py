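"""Morlet wavelet time-frequency analysis, theta epochs, relative power.

The canonical decomposition is a bank of complex Morlet wavelets linearly
spaced over a frequency range (100 wavelets over 2-100 Hz for power spectra;
65 over 20-150 Hz for the cycle-by-cycle gamma analysis).  Each wavelet is a
Gaussian-windowed complex exponential with ``n_cycles`` cycles inside one
temporal standard deviation band (sigma_t = n_cycles / (2 pi f)); kernels are
L1-normalized and doubled so that convolution with a pure cosine of amplitude
A returns magnitude A at the centre frequency, making power read directly in
microvolts squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dsp import bandpass, find_runs, intervals_to_mask, theta_delta_ratio
from .errors import InsufficientDataError, ParameterError
from .io import ChannelMap, LfpRecording, SpeedTrace


@dataclass(frozen=True)
class WaveletBank:
    center_freqs_hz: np.ndarray
    n_cycles: float
    rate_hz: float
    #: 'amplitude' scales kernels so a pure cosine of amplitude A returns
    #: magnitude A (power reads in uV^2); 'energy' (unit-L2) equalizes the
    #: response to white noise across centre frequencies instead.
    norm: str = "amplitude"

    def __post_init__(self):
        freqs = np.asarray(self.center_freqs_hz, dtype=float)
        object.__setattr__(self, "center_freqs_hz", freqs)
        if np.any(np.diff(freqs) <= 0):
            raise ParameterError("center frequencies must be strictly increasing")
        if freqs[0] <= 0 or freqs[-1] >= self.rate_hz / 2.0:
            raise ParameterError("center frequencies must lie in (0, Nyquist)")
        if self.n_cycles < 3:
            raise ParameterError("n_cycles must be >= 3")
        if self.norm not in ("amplitude", "energy"):
            raise ParameterError(f"unknown norm {self.norm!r}")

    def kernel(self, freq_hz: float) -> np.ndarray:
        """Complex Morlet kernel at one centre frequency (support +-4 sigma)."""
        sigma_t = self.n_cycles / (2.0 * np.pi * freq_hz)
        half = int(np.ceil(4.0 * sigma_t * self.rate_hz))
        t = np.arange(-half, half + 1) / self.rate_hz
        gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
        kern = gauss * np.exp(2j * np.pi * freq_hz * t)
        if self.norm == "amplitude":
            return 2.0 * kern / gauss.sum()
        return kern / np.sqrt(np.sum(np.abs(kern) ** 2))


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Instantaneous power (uV^2) and phase (radians in (-pi, pi]) per
    (frequency, time); ``edge_samples[f]`` samples at each end lie inside the
    wavelet half-support and should be treated as unreliable."""
    power: np.ndarray
    phase: np.ndarray
    freqs_hz: np.ndarray
    rate_hz: float
    edge_samples: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.power.shape[1]


@dataclass(frozen=True)
class ThetaEpoch:
    start_s: float
    end_s: float
    mean_ratio: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RelativePowerSpectrum:
    """Power per frequency expressed as percent of the total spectrum."""
    freqs_hz: np.ndarray
    relative_power_percent: np.ndarray

    def __post_init__(self):
        rel = np.asarray(self.relative_power_percent, dtype=float)
        object.__setattr__(self, "relative_power_percent", rel)
        if np.any(rel < 0):
            raise ParameterError("relative power must be non-negative")


@dataclass(frozen=True)
class ThetaEpochParams:
    theta_band: tuple = (6.0, 10.0)
    delta_band: tuple = (1.0, 4.0)
    ratio_threshold: float = 2.0
    window_s: float = 1.0
    min_duration_s: float = 1.0
    locomotion_speed_cm_s: float = 2.0


# ---------------------------------------------------------------------------

def make_bank(fmin_hz: float, fmax_hz: float, n: int, n_cycles: float = 6.0,
              rate_hz: float = 1034.0, norm: str = "amplitude") -> WaveletBank:
    """Linearly spaced Morlet bank, endpoints inclusive."""
    if n < 2:
        raise ParameterError("a bank needs at least 2 wavelets")
    if not 0 < fmin_hz < fmax_hz:
        raise ParameterError("need 0 < fmin < fmax")
    if fmax_hz >= rate_hz / 2.0:
        raise ParameterError(f"fmax {fmax_hz} Hz reaches Nyquist {rate_hz / 2.0} Hz")
    return WaveletBank(center_freqs_hz=np.linspace(fmin_hz, fmax_hz, n),
                       n_cycles=n_cycles, rate_hz=rate_hz, norm=norm)


def wavelet_transform(signal: np.ndarray, bank: WaveletBank) -> TimeFrequencyMap:
    """Convolve one channel with every wavelet of the bank."""
    x = np.asarray(signal, dtype=float)
    n = x.size
    n_f = bank.center_freqs_hz.size
    power = np.empty((n_f, n))
    phase = np.empty((n_f, n))
    edges = np.empty(n_f, dtype=int)
    for i, f in enumerate(bank.center_freqs_hz):
        kern = bank.kernel(f)
        if kern.size > n:
            raise InsufficientDataError(
                f"signal ({n} samples) shorter than the {f:.1f} Hz wavelet "
                f"support ({kern.size} samples)")
        w = sps.fftconvolve(x, kern, mode="same")
        power[i] = np.abs(w) ** 2
        phase[i] = np.angle(w)
        edges[i] = kern.size // 2
    return TimeFrequencyMap(power=power, phase=phase,
                            freqs_hz=bank.center_freqs_hz.copy(),
                            rate_hz=bank.rate_hz, edge_samples=edges)


def wavelet_amplitude(signal: np.ndarray, bank: WaveletBank) -> np.ndarray:
    """Instantaneous amplitude (|W|) per (frequency, time); lighter than a
    full TimeFrequencyMap when phase is not needed."""
    x = np.asarray(signal, dtype=float)
    out = np.empty((bank.center_freqs_hz.size, x.size))
    for i, f in enumerate(bank.center_freqs_hz):
        out[i] = np.abs(sps.fftconvolve(x, bank.kernel(f), mode="same"))
    return out


# ---------------------------------------------------------------------------

def detect_theta_epochs(lfp: np.ndarray, rate_hz: float, speed: SpeedTrace,
                        params: ThetaEpochParams = ThetaEpochParams()) -> list:
    """Maximal intervals with theta/delta power ratio above threshold while
    the animal is walking/running, each at least ``min_duration_s`` long."""
    ratio = theta_delta_ratio(lfp, rate_hz, params.theta_band,
                              params.delta_band, params.window_s)
    t = np.arange(lfp.size) / rate_hz
    v = speed.at(t)
    mask = (ratio > params.ratio_threshold) & (v > params.locomotion_speed_cm_s)
    epochs = []
    for i0, i1 in find_runs(mask):
        if (i1 - i0) / rate_hz >= params.min_duration_s:
            epochs.append(ThetaEpoch(start_s=i0 / rate_hz, end_s=i1 / rate_hz,
                                     mean_ratio=float(ratio[i0:i1].mean())))
    return epochs


def relative_power(tf: TimeFrequencyMap, epochs) -> RelativePowerSpectrum:
    """Time-averaged wavelet power over the epoch samples, normalized so the
    spectrum sums to 100 percent."""
    mask = intervals_to_mask(epochs, tf.n_samples, tf.rate_hz)
    if not mask.any():
        raise InsufficientDataError("epochs cover no samples")
    mean_power = tf.power[:, mask].mean(axis=1)
    total = mean_power.sum()
    if total <= 0:
        raise InsufficientDataError("zero total power over the epochs")
    return RelativePowerSpectrum(freqs_hz=tf.freqs_hz.copy(),
                                 relative_power_percent=100.0 * mean_power / total)


def band_relative_power(spectrum: RelativePowerSpectrum, band: tuple) -> float:
    """Summed relative power over bins whose centre lies inside the band."""
    lo, hi = band
    f = spectrum.freqs_hz
    if hi < f[0] or lo > f[-1]:
        raise ParameterError(f"band {band} outside spectrum range "
                             f"[{f[0]}, {f[-1]}] Hz")
    sel = (f >= lo) & (f <= hi)
    return float(spectrum.relative_power_percent[sel].sum())


def laminar_theta_profile(rec: LfpRecording, cmap: ChannelMap, epochs,
                          reference_channel,
                          theta_band: tuple = (6.0, 10.0)) -> pd.DataFrame:
    """Per-channel theta power and circular-mean phase shift vs a reference.

    Phase differences are computed from the analytic signal of the theta-band
    LFP and averaged circularly; shifts are reported in degrees in
    (-180, 180].  Returns a DataFrame (channel_id, layer, theta_power_uv2,
    phase_shift_deg).
    """
    reference_channel = str(reference_channel)
    if reference_channel not in rec.channel_ids:
        raise KeyError(reference_channel)
    mask = intervals_to_mask(epochs, rec.n_samples, rec.rate_hz,
                             t_start_s=rec.t_start_s)
    if not mask.any():
        raise InsufficientDataError("epochs cover no samples")
    analytic = sps.hilbert(bandpass(rec.samples, rec.rate_hz, theta_band),
                           axis=-1)
    ref = analytic[rec.channel_ids.index(reference_channel)]
    rows = []
    for i, cid in enumerate(rec.channel_ids):
        power = float(np.mean(np.abs(analytic[i, mask]) ** 2) / 2.0)
        dphi = np.angle(analytic[i, mask] * np.conj(ref[mask]))
        shift = np.degrees(np.angle(np.mean(np.exp(1j * dphi))))
        if shift <= -180.0:
            shift += 360.0
        rows.append({"channel_id": cid, "layer": cmap[cid].layer,
                     "theta_power_uv2": power, "phase_shift_deg": float(shift)})
    return pd.DataFrame(rows)
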