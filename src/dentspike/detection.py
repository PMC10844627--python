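"""Dentate-spike peak detection with optional artifact mitigation.

The detector finds peaks of the 1–200 Hz band-passed hilar LFP that exceed
seven times the median absolute filtered amplitude and are at least 50 ms
apart, then re-aligns each peak to the raw-LFP maximum within a 20-ms window
(the band-pass is zero-phase, but slow components removed by the filter still
shift the apparent peak).  Two optional mitigation stages bracket the core
detector: subtraction of a reference channel beforehand (cancels common-mode
transients) and Tukey-fence exclusion of outlier peak amplitudes afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigError
from .io import Recording, make_event_table

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    band: tuple = (1.0, 200.0)       # Hz
    filter_order: int = 4
    threshold_multiplier: float = 7.0
    min_spacing_ms: float = 50.0
    offset_window_ms: float = 20.0   # full width of the raw-LFP re-alignment window
    reference_channel: object = None # channel id, or list of ids (their mean)
    apply_tukey: bool = True

    def __post_init__(self):
        low, high = self.band
        if not (0 < low < high):
            raise ConfigError(f"invalid band {self.band}")
        if self.threshold_multiplier <= 0:
            raise ConfigError("threshold_multiplier must be positive")
        if self.min_spacing_ms <= 0:
            raise ConfigError("min_spacing_ms must be positive")


@dataclass
class TukeyFences:
    q1: float
    q3: float
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self):
        iqr = self.q3 - self.q1
        self.lower = self.q1 - 1.5 * iqr
        self.upper = self.q3 + 1.5 * iqr


def subtract_reference(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Elementwise target minus reference (cancels common-mode artifacts)."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if target.shape != reference.shape:
        raise ConfigError(
            f"target and reference lengths differ: {target.shape} vs {reference.shape}"
        )
    return target - reference


def bandpass_filter(x: np.ndarray, fs: float, cfg: DetectionConfig = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward), same length out."""
    cfg = cfg or DetectionConfig()
    low, high = cfg.band
    if high >= fs / 2:
        raise ConfigError(f"band edge {high} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(cfg.filter_order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _enforce_spacing(indices: np.ndarray, amplitudes: np.ndarray,
                     min_gap_samples: float) -> np.ndarray:
    """Iteratively drop the globally smallest peak involved in any spacing
    violation until all surviving peaks are >= min_gap apart.  Returns a keep
    mask over the input arrays (assumed sorted by index)."""
    keep = np.ones(indices.size, dtype=bool)
    while True:
        alive = np.flatnonzero(keep)
        if alive.size < 2:
            return keep
        gaps = np.diff(indices[alive])
        viol = np.flatnonzero(gaps < min_gap_samples)
        if viol.size == 0:
            return keep
        # peaks touching at least one violating pair
        offenders = np.unique(np.concatenate([viol, viol + 1]))
        cand = alive[offenders]
        # smallest amplitude loses; ties resolved toward the later peak
        order = np.lexsort((-indices[cand], amplitudes[cand]))
        keep[cand[order[0]]] = False


def detect_peaks(filtered: np.ndarray, fs: float,
                 cfg: DetectionConfig = None) -> np.ndarray:
    """Local maxima above ``threshold_multiplier x median(|filtered|)``, with
    iterative small-peak elimination until all pairs are >= min_spacing apart."""
    cfg = cfg or DetectionConfig()
    filtered = np.asarray(filtered, dtype=float)
    threshold = cfg.threshold_multiplier * np.median(np.abs(filtered))
    idx, _ = sps.find_peaks(filtered, height=threshold if threshold > 0 else None)
    if threshold == 0:
        idx = idx[filtered[idx] > 0]
    if idx.size == 0:
        return idx
    keep = _enforce_spacing(idx, filtered[idx], cfg.min_spacing_ms * fs / 1000.0)
    return idx[keep]


def correct_peak_offsets(raw: np.ndarray, peaks: np.ndarray, fs: float,
                         cfg: DetectionConfig = None):
    """Move each filtered-LFP peak to the raw-LFP argmax within the offset
    window (±offset_window/2 around it); earliest sample wins ties.  Peaks
    that collapse onto the same corrected sample are merged keeping the larger
    raw amplitude.  Returns (corrected indices, offsets in ms)."""
    cfg = cfg or DetectionConfig()
    raw = np.asarray(raw, dtype=float)
    half = int(round(cfg.offset_window_ms / 2.0 * fs / 1000.0))
    corrected, offsets = [], []
    for p in np.asarray(peaks, dtype=int):
        lo = max(0, p - half)
        hi = min(raw.size, p + half + 1)
        new = lo + int(np.argmax(raw[lo:hi]))   # argmax takes the earliest tie
        corrected.append(new)
        offsets.append((new - p) * 1000.0 / fs)
    corrected = np.asarray(corrected, dtype=int)
    offsets = np.asarray(offsets, dtype=float)
    # merge duplicates, keeping the occurrence with larger raw amplitude
    # (duplicates have equal raw amplitude by construction; keep the first)
    _, first = np.unique(corrected, return_index=True)
    order = np.sort(first)
    return corrected[order], offsets[order]


def tukey_filter(amplitudes: Sequence[float]):
    """Keep-mask under Tukey's fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics.  Fewer than
    four amplitudes pass through unfiltered (fences undefined -> None).
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 4:
        return np.ones(amps.size, dtype=bool), None
    q1, q3 = np.percentile(amps, [25, 75])  # linear interpolation ("type 7")
    fences = TukeyFences(q1=float(q1), q3=float(q3))
    mask = (amps >= fences.lower) & (amps <= fences.upper)
    return mask, fences


def detect_dentate_spikes(rec: Recording, channel, cfg: DetectionConfig = None) -> pd.DataFrame:
    """Full detection flowchart on one target channel.

    reference subtraction (optional) -> band-pass -> thresholded peaks with
    spacing -> raw-peak offset correction (spacing re-checked) -> Tukey-fence
    outlier exclusion (optional).  Excluded events stay in the table with
    ``excluded=True`` and reason ``tukey_high`` / ``tukey_low``.
    """
    cfg = cfg or DetectionConfig()
    raw = rec.get_channel(channel)

    det_sig = raw
    if cfg.reference_channel is not None:
        refch = cfg.reference_channel
        if isinstance(refch, (list, tuple)):
            ref = np.mean([rec.get_channel(c) for c in refch], axis=0)
        else:
            ref = rec.get_channel(refch)
        det_sig = subtract_reference(raw, ref)

    filtered = bandpass_filter(det_sig, rec.fs, cfg)
    peaks = detect_peaks(filtered, rec.fs, cfg)
    corrected, offsets = correct_peak_offsets(raw, peaks, rec.fs, cfg)

    # offset correction can push peaks closer together: re-enforce spacing on
    # the corrected positions using raw amplitudes
    amps = raw[corrected]
    keep = _enforce_spacing(corrected, amps, cfg.min_spacing_ms * rec.fs / 1000.0)
    corrected, offsets, amps = corrected[keep], offsets[keep], amps[keep]

    excluded = np.zeros(corrected.size, dtype=bool)
    reasons = [""] * corrected.size
    if cfg.apply_tukey:
        mask, fences = tukey_filter(amps)
        excluded = ~mask
        if fences is not None:
            reasons = [
                "" if m else ("tukey_high" if a > fences.upper else "tukey_low")
                for m, a in zip(mask, amps)
            ]
    events = make_event_table(corrected, channel, amps, offsets, excluded, reasons)
    logger.info(
        "detected %d peaks on channel %r (%d kept, %d excluded by Tukey fences)",
        corrected.size, channel, int((~excluded).sum()), int(excluded.sum()),
    )
    return events
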