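"""Independent reference implementations (oracles) used by the tests.

These deliberately re-derive results with naive, loop-based logic so that
agreement with the package's vectorized implementations is informative.
"""

import numpy as np

from hippolfp.dsp import bandpass, smoothed_envelope
from hippolfp.synth import _windowed_tone


def naive_detect_ripples(env_z, rate_hz, periods, thresh=3.0, min_ms=15.0,
                         boundary=1.0, merge_gap_ms=40.0):
    """Sample-by-sample state-machine ripple detector on a standardized
    envelope; returns (start_idx, end_idx) half-open index pairs."""
    events = []
    for p in periods:
        s = p[0] if isinstance(p, tuple) else p.start_s
        e = p[1] if isinstance(p, tuple) else p.end_s
        i0 = max(0, int(np.ceil(s * rate_hz)))
        i1 = min(env_z.size, int(np.ceil(e * rate_hz)))
        j = i0
        while j < i1:
            if env_z[j] >= thresh:
                k = j
                while k < i1 and env_z[k] >= thresh:
                    k += 1
                if (k - j) >= int(round(min_ms * 1e-3 * rate_hz)):
                    a, b = j, k
                    while a > i0 and env_z[a - 1] >= boundary:
                        a -= 1
                    while b < i1 and env_z[b] >= boundary:
                        b += 1
                    events.append((a, b))
                j = k
            else:
                j += 1
    events.sort()
    merged = []
    for a, b in events:
        if merged and (a - merged[-1][1]) < merge_gap_ms * 1e-3 * rate_hz:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def brute_force_burst_kinds(peak_times, window_s=0.2):
    """Chain sizes by exhaustive pairwise scan over sorted peak times."""
    peaks = sorted(peak_times)
    sizes, current = [], 1
    for prev, nxt in zip(peaks, peaks[1:]):
        if nxt - prev <= window_s:
            current += 1
        else:
            sizes.append(current)
            current = 1
    if peaks:
        sizes.append(current)
    return sizes


def holm_sidak_oracle(pvalues, alpha=0.05):
    """Step-down Holm-Sidak decisions recomputed from first principles."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        adjusted_alpha = 1.0 - (1.0 - alpha) ** (1.0 / (m - rank))
        if p[idx] <= adjusted_alpha:
            reject[idx] = True
        else:
            break
    return reject


def burst_background(rate_hz=1034.0, duration_s=30.0, seed=0, sd_uv=2.0):
    """Band-limited noise background for controlled burst fixtures."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * rate_hz)
    return bandpass(rng.standard_normal(n), rate_hz, (100.0, 300.0)) * sd_uv


def add_burst(x, rate_hz, t_center_s, dur_ms, freq_hz, amp_z,
              band=(150.0, 250.0), sigma_ms=4.0, window="hann"):
    """Add a windowed tone whose nominal amplitude is ``amp_z`` baseline-SD
    units of the background's smoothed band envelope (0.85 compensates the
    envelope smoothing loss of a short Hann burst)."""
    env = smoothed_envelope(bandpass(x, rate_hz, band), rate_hz, sigma_ms)
    amp = (env.mean() + amp_z * env.std()) / 0.85
    i0, w = _windowed_tone(rate_hz, t_center_s, dur_ms * 1e-3, freq_hz, amp,
                           x.size, window=window)
    out = x.copy()
    out[i0:i0 + w.size] += w
    return out
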