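"""Shared signal-processing primitives: band-pass filtering, envelopes, runs.

All band-pass filtering in the package is zero-phase (forward-backward)
Butterworth, order 4 per direction, so phase relationships between bands are
preserved — a requirement for every phase-based analysis downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError


def bandpass(x: np.ndarray, rate_hz: float, band: tuple, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    lo, hi = band
    nyq = rate_hz / 2.0
    if not 0 < lo < hi:
        raise ParameterError(f"band must satisfy 0 < low < high, got {band}")
    if hi >= nyq:
        raise ParameterError(f"band {band} exceeds Nyquist frequency {nyq} Hz")
    sos = sps.butter(order, (lo, hi), btype="band", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def smoothed_envelope(x: np.ndarray, rate_hz: float, sigma_ms: float) -> np.ndarray:
    """Magnitude of the analytic signal, Gaussian-smoothed (sigma in ms)."""
    env = np.abs(sps.hilbert(x))
    if sigma_ms > 0:
        env = gaussian_filter1d(env, sigma=sigma_ms * 1e-3 * rate_hz, axis=-1)
    return env


def intervals_to_mask(intervals, n_samples: int, rate_hz: float,
                      t_start_s: float = 0.0) -> np.ndarray:
    """Boolean sample mask from a list of (start_s, end_s) half-open intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for iv in intervals:
        s, e = _interval_bounds(iv)
        i0 = max(0, int(np.ceil((s - t_start_s) * rate_hz)))
        i1 = min(n_samples, int(np.ceil((e - t_start_s) * rate_hz)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def _interval_bounds(iv) -> tuple:
    """Accept (start, end) tuples or objects with start_s / end_s attributes."""
    if hasattr(iv, "start_s"):
        return float(iv.start_s), float(iv.end_s)
    s, e = iv
    return float(s), float(e)


def find_runs(mask: np.ndarray) -> list:
    """Half-open index runs [i0, i1) where a boolean mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def sliding_band_power(x: np.ndarray, rate_hz: float, band: tuple,
                       window_s: float = 1.0) -> np.ndarray:
    """Band-limited power in a sliding window (moving average of the squared
    band-passed signal); same length as the input."""
    filt = bandpass(x, rate_hz, band)
    win = max(1, int(round(window_s * rate_hz)))
    return sps.convolve(filt ** 2, np.ones(win) / win, mode="same")


def theta_delta_ratio(x: np.ndarray, rate_hz: float,
                      theta_band: tuple = (6.0, 10.0),
                      delta_band: tuple = (1.0, 4.0),
                      window_s: float = 1.0) -> np.ndarray:
    """Per-sample theta/delta power ratio used for brain-state segmentation.

    High values mark theta states (locomotion/REM-like); low values mark
    large-irregular-activity states where sharp-wave ripples occur.
    """
    theta = sliding_band_power(x, rate_hz, theta_band, window_s)
    delta = sliding_band_power(x, rate_hz, delta_band, window_s)
    return theta / np.maximum(delta, np.finfo(float).tiny)
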