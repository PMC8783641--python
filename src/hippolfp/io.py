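"""Containers and I/O for laminar LFP recordings.

A recording is a channels x time array of extracellular voltage (microvolts)
with a sampling rate and an ordered list of channel ids.  A channel map is a
JSON sidecar describing probe geometry (shank, depth index, vertical spacing)
and the anatomical layer each site sits in; layer labels select the stratum
pyramidale / radiatum channels that the event detectors operate on.

On-disk container (HDF5):

* ``/lfp`` — channels x samples, float32 microvolts, or int16 with a
  ``scale_uv`` attribute (microvolts per bit); attributes ``rate_hz``,
  ``t_start_s``, ``channel_ids``.
* ``/speed`` — group with ``times_s`` and ``speed_cm_s`` datasets and a
  ``frame_rate_hz`` attribute (head-tracking runs at 50 frames/s).

The probe map lives in ``<stem>.probe.json`` next to the HDF5 file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .errors import FormatError, ParameterError

#: Anatomical layer labels along the CA1-dentate axis (top to bottom).
LAYERS = (
    "str_oriens",
    "str_pyramidale",
    "str_radiatum",
    "str_LM",
    "dg_moleculare",
    "dg_granule",
    "hilus",
    "unknown",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LfpRecording:
    """Multi-channel LFP time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Extracellular voltage in microvolts.
    rate_hz : float
        Sampling rate.
    channel_ids : tuple of str
        Unique identifiers aligned with the rows of ``samples``.
    t_start_s : float
        Time of the first sample, seconds.
    """

    samples: np.ndarray
    rate_hz: float
    channel_ids: tuple
    t_start_s: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[None, :]
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_ids", tuple(str(c) for c in self.channel_ids))
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if len(self.channel_ids) != samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_ids)} channel ids for {samples.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise FormatError("channel_ids must be unique")
        if samples.size and not np.all(np.isfinite(samples)):
            raise FormatError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, channel_id) -> np.ndarray:
        """Return the sample row for one channel id."""
        return self.samples[self.channel_ids.index(str(channel_id))]


@dataclass(frozen=True)
class ChannelInfo:
    channel_id: str
    shank: int
    depth: int
    spacing_mm: float
    layer: str = "unknown"

    def __post_init__(self):
        object.__setattr__(self, "channel_id", str(self.channel_id))
        if self.spacing_mm <= 0:
            raise FormatError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer label {self.layer!r}")


@dataclass(frozen=True)
class ChannelMap:
    """Probe geometry and anatomical labels, one entry per recording channel."""

    channels: tuple

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate channel ids in map")

    @property
    def channel_ids(self) -> tuple:
        return tuple(c.channel_id for c in self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, channel_id) -> ChannelInfo:
        for c in self.channels:
            if c.channel_id == str(channel_id):
                return c
        raise KeyError(channel_id)

    def channels_in_layer(self, layer: str) -> tuple:
        return tuple(c.channel_id for c in self.channels if c.layer == layer)

    def by_shank(self) -> dict:
        """Channels grouped by shank, sorted by depth index."""
        shanks: dict = {}
        for c in self.channels:
            shanks.setdefault(c.shank, []).append(c)
        return {k: sorted(v, key=lambda c: c.depth) for k, v in sorted(shanks.items())}

    def check_against(self, rec: LfpRecording) -> None:
        if len(self.channels) != rec.n_channels:
            raise FormatError(
                f"channel map has {len(self.channels)} entries but recording "
                f"has {rec.n_channels} rows"
            )
        if set(self.channel_ids) != set(rec.channel_ids):
            raise FormatError("channel map ids do not match recording ids")


@dataclass(frozen=True)
class SpeedTrace:
    """Animal running-speed trace from head tracking (default 50 frames/s)."""

    times_s: np.ndarray
    speed_cm_s: np.ndarray
    frame_rate_hz: float = 50.0

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.speed_cm_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "speed_cm_s", v)
        if t.shape != v.shape:
            raise FormatError("times_s and speed_cm_s must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise FormatError("times_s must be strictly increasing")
        if np.any(v < 0):
            raise FormatError("speeds must be non-negative")

    def at(self, times_s: np.ndarray) -> np.ndarray:
        """Speed linearly interpolated at arbitrary times."""
        return np.interp(times_s, self.times_s, self.speed_cm_s)


# ---------------------------------------------------------------------------
# Container read / write
# ---------------------------------------------------------------------------

def _probe_path(path) -> Path:
    return Path(path).with_suffix(".probe.json")


def write_recording(rec: LfpRecording, cmap: ChannelMap, path,
                    speed: SpeedTrace | None = None,
                    dtype: str = "float32", scale_uv: float = 0.195) -> None:
    """Write a recording, its probe map, and optionally a speed trace.

    ``dtype='int16'`` stores scaled integers with ``scale_uv`` microvolts per
    bit (the acquisition-system convention); float32 stores microvolts
    directly and round-trips bit-exactly.
    """
    cmap.check_against(rec)
    path = Path(path)
    with h5py.File(path, "w") as f:
        if dtype == "float32":
            f.create_dataset("lfp", data=rec.samples.astype(np.float32))
        elif dtype == "int16":
            q = np.clip(np.round(rec.samples / scale_uv), -32768, 32767)
            ds = f.create_dataset("lfp", data=q.astype(np.int16))
            ds.attrs["scale_uv"] = float(scale_uv)
        else:
            raise ParameterError(f"unsupported storage dtype {dtype!r}")
        f["lfp"].attrs["rate_hz"] = float(rec.rate_hz)
        f["lfp"].attrs["t_start_s"] = float(rec.t_start_s)
        f["lfp"].attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        if speed is not None:
            g = f.create_group("speed")
            g.create_dataset("times_s", data=speed.times_s)
            g.create_dataset("speed_cm_s", data=speed.speed_cm_s)
            g.attrs["frame_rate_hz"] = float(speed.frame_rate_hz)
    probe = [
        {"channel_id": c.channel_id, "shank": c.shank, "depth": c.depth,
         "spacing_mm": c.spacing_mm, "layer": c.layer}
        for c in cmap.channels
    ]
    _probe_path(path).write_text(json.dumps(probe, indent=1))


def read_recording(path) -> tuple:
    """Read ``(LfpRecording, ChannelMap)`` from the HDF5 container + sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        ds = f["lfp"]
        data = ds[()]
        if data.dtype == np.int16:
            data = data.astype(np.float64) * float(ds.attrs["scale_uv"])
        else:
            data = data.astype(np.float64)
        rec = LfpRecording(
            samples=data,
            rate_hz=float(ds.attrs["rate_hz"]),
            channel_ids=tuple(
                c.decode() if isinstance(c, bytes) else str(c)
                for c in ds.attrs["channel_ids"]
            ),
            t_start_s=float(ds.attrs["t_start_s"]),
        )
    probe_path = _probe_path(path)
    if not probe_path.exists():
        raise FileNotFoundError(probe_path)
    entries = json.loads(probe_path.read_text())
    cmap = ChannelMap(tuple(ChannelInfo(**e) for e in entries))
    cmap.check_against(rec)
    return rec, cmap


def read_speed(path) -> SpeedTrace | None:
    """Read the speed trace stored alongside the LFP, or None if absent."""
    with h5py.File(Path(path), "r") as f:
        if "speed" not in f:
            return None
        g = f["speed"]
        return SpeedTrace(
            times_s=g["times_s"][()],
            speed_cm_s=g["speed_cm_s"][()],
            frame_rate_hz=float(g.attrs["frame_rate_hz"]),
        )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def antialias_cutoff_hz(target_rate_hz: float) -> float:
    """Anti-alias low-pass cutoff used before downsampling.

    The cutoff is 40% of the output sampling rate, so downsampling to the
    standard 1034 Hz analysis rate uses a 413.6 Hz cutoff.
    """
    return 0.4 * target_rate_hz


def lowpass_downsample(rec: LfpRecording, target_rate_hz: float,
                       order: int = 8) -> LfpRecording:
    """Zero-phase anti-alias low-pass then polyphase resample.

    A Butterworth low-pass (``order`` poles, applied forward and backward, so
    no group delay) at :func:`antialias_cutoff_hz` precedes a rational
    polyphase resampling; non-integer rate ratios are handled by the
    numerator/denominator of the reduced fraction.  The default order keeps
    leakage at 500 Hz below 5% when downsampling to the 1034 Hz analysis
    rate.  The input recording is not modified.
    """
    if target_rate_hz >= rec.rate_hz:
        raise ParameterError(
            f"target rate {target_rate_hz} must be below recording rate {rec.rate_hz}"
        )
    cutoff = antialias_cutoff_hz(target_rate_hz)
    sos = sps.butter(order, cutoff, btype="low", fs=rec.rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=-1)
    frac = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(1_000_000)
    out = sps.resample_poly(filtered, frac.numerator, frac.denominator, axis=-1)
    return replace(rec, samples=out, rate_hz=float(target_rate_hz))


def exclude_channels(rec: LfpRecording, cmap: ChannelMap,
                     bad_ids: Sequence) -> tuple:
    """Drop noisy channels from both the recording and the map.

    Remaining channels keep their original order.  Unknown ids raise KeyError.
    """
    bad = {str(b) for b in bad_ids}
    unknown = bad - set(rec.channel_ids)
    if unknown:
        raise KeyError(f"unknown channel ids: {sorted(unknown)}")
    keep = [i for i, c in enumerate(rec.channel_ids) if c not in bad]
    new_rec = replace(
        rec,
        samples=rec.samples[keep],
        channel_ids=tuple(rec.channel_ids[i] for i in keep),
    )
    new_map = ChannelMap(tuple(c for c in cmap.channels if c.channel_id not in bad))
    return new_rec, new_map
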