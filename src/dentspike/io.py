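"""Recording / event-table / waveform I-O.

A :class:`Recording` holds a multichannel laminar LFP in millivolts, with the
channel order running from the most superficial electrode (closest to CA1) to
the deepest.  Recordings are stored on disk as flat little-endian
channel-interleaved binary plus a JSON sidecar describing the layout; detected
events travel as plain CSV tables with a fixed column set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError

#: Exact column set (and order) of an event table CSV.
EVENT_COLUMNS = [
    "event_id",
    "peak_sample",
    "channel",
    "peak_amplitude_mv",
    "offset_ms",
    "excluded",
    "excluded_reason",
    "label_csdbc",
    "label_wfbc",
    "posterior",
]

_SIDECAR_KEYS = ["dtype", "n_channels", "fs_hz", "channel_order", "channel_spacing_um"]


@dataclass
class Recording:
    """Multichannel LFP in mV, channels ordered superficial -> deep."""

    samples: np.ndarray            # (n_channels, n_samples), mV
    fs: float                      # Hz
    channel_order: list            # channel ids, most superficial first
    channel_spacing: float = 50.0  # µm between adjacent electrodes
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ConfigError("samples must be a 2-D [channel x time] array")
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        self.channel_order = list(self.channel_order)
        if len(set(self.channel_order)) != len(self.channel_order):
            raise ConfigError("channel_order contains duplicates")
        if len(self.channel_order) != self.samples.shape[0]:
            raise ConfigError(
                f"channel_order length {len(self.channel_order)} != "
                f"channel count {self.samples.shape[0]}"
            )
        if not np.isfinite(self.samples).all():
            raise ConfigError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, channel_id) -> int:
        """Row index of a channel id in depth order."""
        try:
            return self.channel_order.index(channel_id)
        except ValueError:
            raise ConfigError(f"unknown channel id {channel_id!r}") from None

    def get_channel(self, channel_id) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]


@dataclass
class WaveformMatrix:
    """Peak-aligned LFP snippets: one row per event, columns spanning *window* ms."""

    values: np.ndarray             # (n_events, n_cols), mV
    window: tuple                  # (start_ms, end_ms) relative to peak
    fs: float
    event_ids: np.ndarray
    dropped_event_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.event_ids = np.asarray(self.event_ids, dtype=int)
        start, end = self.window
        expected = round((end - start) * self.fs / 1000.0) + 1
        if self.values.size and self.values.shape[1] != expected:
            raise ConfigError(
                f"window {self.window} at fs={self.fs} implies {expected} columns, "
                f"matrix has {self.values.shape[1]}"
            )

    @property
    def n_events(self) -> int:
        return 0 if self.values.size == 0 else self.values.shape[0]

    @property
    def n_cols(self) -> int:
        start, end = self.window
        return round((end - start) * self.fs / 1000.0) + 1

    @property
    def peak_column(self) -> int:
        """Column index of peak-relative time zero."""
        return self.column_of(0.0)

    def column_of(self, t_ms: float) -> int:
        start, _ = self.window
        return round((t_ms - start) * self.fs / 1000.0)

    @property
    def times_ms(self) -> np.ndarray:
        start, _ = self.window
        return start + np.arange(self.n_cols) * 1000.0 / self.fs


# ---------------------------------------------------------------------------
# binary recording I/O


def read_recording(path, sidecar) -> Recording:
    """Read a flat binary recording described by its JSON sidecar.

    The binary payload is little-endian and channel-interleaved: sample t of
    all channels precedes sample t+1.  int16 payloads are scaled to mV by the
    sidecar's ``scale_mv``; float64 payloads are already in mV.
    """
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        sc = json.load(fh)
    for key in _SIDECAR_KEYS:
        if key not in sc:
            raise ConfigError(f"sidecar missing required key {key!r}")
    dtype = sc["dtype"]
    n_channels = int(sc["n_channels"])
    if dtype == "int16":
        np_dtype = np.dtype("<i2")
        if "scale_mv" not in sc:
            raise ConfigError("int16 sidecar requires 'scale_mv' (mV per bit)")
    elif dtype == "float64":
        np_dtype = np.dtype("<f8")
    else:
        raise ConfigError(f"unsupported dtype {dtype!r} (int16 or float64)")

    raw = np.fromfile(path, dtype=np_dtype)
    if raw.size % n_channels != 0:
        raise FormatError(
            f"file length {raw.size} samples not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T
    if dtype == "int16":
        data = data.astype(np.float64) * float(sc["scale_mv"])
    else:
        data = data.astype(np.float64)
    return Recording(
        samples=data,
        fs=float(sc["fs_hz"]),
        channel_order=list(sc["channel_order"]),
        channel_spacing=float(sc["channel_spacing_um"]),
        meta={k: v for k, v in sc.items() if k not in _SIDECAR_KEYS + ["scale_mv"]},
    )


def write_recording(rec: Recording, path, sidecar, dtype: str = "float64",
                    scale_mv: float = 1e-3) -> None:
    """Write a recording as flat binary + JSON sidecar (inverse of read)."""
    sc = {
        "dtype": dtype,
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "channel_order": rec.channel_order,
        "channel_spacing_um": rec.channel_spacing,
    }
    if dtype == "float64":
        payload = rec.samples.T.astype("<f8")
    elif dtype == "int16":
        sc["scale_mv"] = scale_mv
        payload = np.round(rec.samples.T / scale_mv).astype("<i2")
    else:
        raise ConfigError(f"unsupported dtype {dtype!r}")
    payload.tofile(path)
    with open(sidecar, "w") as fh:
        json.dump(sc, fh, indent=1)


# ---------------------------------------------------------------------------
# event tables


def make_event_table(peak_samples, channel, peak_amplitudes, offsets_ms=None,
                     excluded=None, excluded_reason=None) -> pd.DataFrame:
    """Assemble a fresh event table (labels unset) from detection output."""
    peak_samples = np.asarray(peak_samples, dtype=int)
    n = peak_samples.size
    df = pd.DataFrame({
        "event_id": np.arange(n, dtype=int),
        "peak_sample": peak_samples,
        "channel": [channel] * n,
        "peak_amplitude_mv": np.asarray(peak_amplitudes, dtype=float),
        "offset_ms": np.zeros(n) if offsets_ms is None else np.asarray(offsets_ms, dtype=float),
        "excluded": np.zeros(n, dtype=bool) if excluded is None else np.asarray(excluded, dtype=bool),
        "excluded_reason": [""] * n if excluded_reason is None else list(excluded_reason),
        "label_csdbc": pd.array([pd.NA] * n, dtype="Int64"),
        "label_wfbc": pd.array([pd.NA] * n, dtype="Int64"),
        "posterior": np.full(n, np.nan),
    })
    return df


def validate_events(events: pd.DataFrame, min_spacing_ms: float = None, fs: float = None):
    """Check column set, label domain and (optionally) per-channel spacing."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    for col in ("label_csdbc", "label_wfbc"):
        vals = events[col].dropna().unique()
        bad = [v for v in vals if int(v) not in (1, 2)]
        if bad:
            raise FormatError(f"{col} contains values outside {{1,2}}: {bad}")
    post = events["posterior"].dropna()
    if ((post < 0) | (post > 1)).any():
        raise FormatError("posterior outside [0, 1]")
    if min_spacing_ms is not None and fs is not None:
        kept = events[~events["excluded"].astype(bool)]
        for _, grp in kept.groupby("channel"):
            ps = np.sort(grp["peak_sample"].to_numpy())
            if ps.size > 1 and np.diff(ps).min() < min_spacing_ms * fs / 1000.0:
                raise FormatError("kept events violate minimum spacing")


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events)
    out = events[EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]]
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"excluded_reason": "string"},
        keep_default_na=True,
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event CSV missing columns: {missing}")
    df["event_id"] = df["event_id"].astype(int)
    df["peak_sample"] = df["peak_sample"].astype(int)
    df["excluded"] = df["excluded"].astype(bool)
    df["excluded_reason"] = df["excluded_reason"].fillna("").astype(str)
    for col in ("label_csdbc", "label_wfbc"):
        df[col] = pd.array(df[col], dtype="Int64")
    validate_events(df)
    return df


# ---------------------------------------------------------------------------
# waveform extraction


def extract_waveforms(rec: Recording, events: pd.DataFrame,
                      window: tuple = (-15.0, 15.0), channel=None,
                      include_excluded: bool = False) -> WaveformMatrix:
    """Cut raw-LFP snippets around each event's peak.

    ``window`` is (start_ms, end_ms) with start <= 0 <= end.  Events whose
    snippet would run past either end of the recording are dropped and
    reported in ``dropped_event_ids`` (never zero-padded).  Snippets come from
    each event's own channel unless ``channel`` overrides it.
    """
    start_ms, end_ms = window
    if not (start_ms <= 0 <= end_ms):
        raise ConfigError(f"window must span the peak, got {window}")
    sel = events if include_excluded else events[~events["excluded"].astype(bool)]
    pre = round(-start_ms * rec.fs / 1000.0)
    post = round(end_ms * rec.fs / 1000.0)
    n_cols = pre + post + 1

    rows, kept_ids, dropped = [], [], []
    for _, ev in sel.iterrows():
        p = int(ev["peak_sample"])
        if p - pre < 0 or p + post >= rec.n_samples:
            dropped.append(int(ev["event_id"]))
            continue
        ch = channel if channel is not None else ev["channel"]
        sig = rec.get_channel(ch)
        rows.append(sig[p - pre: p + post + 1])
        kept_ids.append(int(ev["event_id"]))

    values = np.array(rows, dtype=np.float64) if rows else np.empty((0, n_cols))
    return WaveformMatrix(
        values=values, window=(float(start_ms), float(end_ms)), fs=rec.fs,
        event_ids=np.array(kept_ids, dtype=int),
        dropped_event_ids=np.array(dropped, dtype=int),
    )
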