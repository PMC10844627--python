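"""Delta-state segmentation and DS rate.

DSs occur almost exclusively during sleep-like epochs dominated by delta
(0–5 Hz) activity.  The segmentation decomposes the raw hilar LFP by
empirical mode decomposition (EMD), picks the intrinsic mode function (IMF)
carrying the delta rhythm, and marks a one-minute window "strong delta" when
the delta-band share of that IMF's own spectral power exceeds 0.9.  The DS
rate is then the mean events/min over strong-delta windows only.

The 5th IMF is the conventional delta carrier for 1-kHz rodent LFP; because
the mode an oscillation lands in depends on the broadband content of the
particular recording, an automatic fallback selects the IMF whose spectral
centroid falls inside the delta band whenever IMF-5 does not qualify (the
fallback is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .exceptions import ConfigError, DegenerateInputError

logger = logging.getLogger(__name__)

DELTA_BAND = (0.0, 5.0)


# ---------------------------------------------------------------------------
# empirical mode decomposition


def _local_extrema(x: np.ndarray):
    d = np.diff(x)
    rising = d > 0
    maxima = np.flatnonzero(rising[:-1] & ~rising[1:]) + 1
    minima = np.flatnonzero(~rising[:-1] & rising[1:]) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, kind: str) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored end extrema to
    tame boundary swings."""
    n = x.size
    t = np.arange(n)
    # mirror up to two extrema about each end
    k = min(2, idx.size)
    left_t = -idx[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    tt = np.concatenate([left_t, idx, right_t])
    vv = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    tt, uniq = np.unique(tt, return_index=True)
    return CubicSpline(tt, vv[uniq])(t)


def _sift(x: np.ndarray, sd_tol: float, max_sifts: int) -> Optional[np.ndarray]:
    """One IMF by standard sifting; None when x has too few extrema."""
    h = x
    for _ in range(max_sifts):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        mean_env = 0.5 * (_envelope(h, maxima, "max") + _envelope(h, minima, "min"))
        h_new = h - mean_env
        denom = np.sum(h**2)
        if denom == 0:
            return h_new
        sd = np.sum((h - h_new) ** 2) / denom
        h = h_new
        if sd < sd_tol:
            break
    return h


def decompose_emd(x: np.ndarray, max_imfs: int = 12, sd_tol: float = 0.2,
                  max_sifts: int = 50):
    """Empirical mode decomposition by cubic-spline sifting.

    Returns (imfs, residual) with IMFs ordered fast to slow; their sum plus
    the residual reconstructs the input to numerical precision (sifting only
    ever subtracts, so completeness is exact by construction).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise DegenerateInputError("signal too short for EMD")
    imfs: List[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 4:
            break
        imf = _sift(residual, sd_tol, max_sifts)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs, residual


# ---------------------------------------------------------------------------
# delta power and segmentation


@dataclass
class DeltaSegmentation:
    window_s: float
    rel_power: np.ndarray          # per-window delta/full-band ratio of the IMF
    strong_mask: np.ndarray        # rel_power > threshold
    imf_index: int                 # 1-based index of the IMF used
    delta_band: tuple = DELTA_BAND
    threshold: float = 0.9

    @property
    def n_windows(self) -> int:
        return self.rel_power.size


def _window_slices(n_samples: int, fs: float, window_s: float,
                   min_partial_frac: float = 0.5):
    """Contiguous left-aligned windows; a trailing partial window is kept when
    it covers at least half the nominal length."""
    w = int(round(window_s * fs))
    slices = []
    start = 0
    while start < n_samples:
        end = min(start + w, n_samples)
        if end - start >= min_partial_frac * w:
            slices.append((start, end))
        start += w
    return slices


def _spectrum(seg: np.ndarray, fs: float):
    nperseg = min(seg.size, int(4 * fs))
    return sps.welch(seg, fs=fs, nperseg=nperseg)


def relative_delta_power(imf: np.ndarray, fs: float, band: tuple = DELTA_BAND,
                         window_s: float = 60.0) -> np.ndarray:
    """Per-window ratio of the IMF's band power to its full-band power
    (Welch periodogram, 0 to Nyquist)."""
    imf = np.asarray(imf, dtype=float)
    if imf.size < window_s * fs:
        logger.warning("signal shorter than one %g-s window; using a single "
                       "truncated window", window_s)
        slices = [(0, imf.size)]
    else:
        slices = _window_slices(imf.size, fs, window_s)
    ratios = np.empty(len(slices))
    for i, (a, b) in enumerate(slices):
        f, p = _spectrum(imf[a:b], fs)
        total = np.trapezoid(p, f)
        if total == 0:
            ratios[i] = 0.0
            continue
        inband = (f >= band[0]) & (f <= band[1])
        ratios[i] = np.trapezoid(p[inband], f[inband]) / total
    return np.clip(ratios, 0.0, 1.0)


def segment_delta(ratios: np.ndarray, threshold: float = 0.9,
                  window_s: float = 60.0, imf_index: int = 5,
                  band: tuple = DELTA_BAND) -> DeltaSegmentation:
    """Strong delta iff the relative delta power strictly exceeds the
    threshold (a ratio of exactly 0.9 is weak)."""
    ratios = np.asarray(ratios, dtype=float)
    return DeltaSegmentation(window_s=window_s, rel_power=ratios,
                             strong_mask=ratios > threshold,
                             imf_index=imf_index, delta_band=band,
                             threshold=threshold)


def _spectral_centroid(x: np.ndarray, fs: float) -> float:
    f, p = _spectrum(x, fs)
    total = p.sum()
    return float((f * p).sum() / total) if total > 0 else np.inf


def select_delta_imf(imfs, fs: float, preferred: int = 5,
                     band: tuple = DELTA_BAND) -> int:
    """1-based index of the delta-carrying IMF: the preferred index when its
    spectral centroid lies in the delta band, otherwise the most powerful IMF
    whose centroid does (logged fallback)."""
    if not imfs:
        raise DegenerateInputError("no IMFs to select from")
    centroids = [_spectral_centroid(imf, fs) for imf in imfs]
    if preferred <= len(imfs) and band[0] <= centroids[preferred - 1] <= band[1]:
        return preferred
    in_band = [i for i, c in enumerate(centroids) if band[0] <= c <= band[1]]
    if in_band:
        best = max(in_band, key=lambda i: float(np.sum(imfs[i] ** 2)))
    else:
        best = int(np.argmin([abs(c - band[1] / 2) for c in centroids]))
    logger.info("delta IMF fallback: using IMF-%d (centroid %.2f Hz) instead "
                "of IMF-%d", best + 1, centroids[best], preferred)
    return best + 1


def delta_segmentation(signal: np.ndarray, fs: float, window_s: float = 60.0,
                       threshold: float = 0.9, imf_index: int = 5,
                       auto_select: bool = True) -> DeltaSegmentation:
    """EMD -> delta-IMF selection -> per-window relative delta power -> mask."""
    imfs, _ = decompose_emd(signal)
    if auto_select:
        imf_index = select_delta_imf(imfs, fs, preferred=imf_index)
    if imf_index > len(imfs):
        raise ConfigError(f"requested IMF-{imf_index}, only {len(imfs)} IMFs")
    ratios = relative_delta_power(imfs[imf_index - 1], fs, window_s=window_s)
    return segment_delta(ratios, threshold=threshold, window_s=window_s,
                         imf_index=imf_index)


# ---------------------------------------------------------------------------
# DS rate


@dataclass
class RateResult:
    per_window_rate: np.ndarray    # events/min, one entry per strong window
    mean_rate: float               # mean over strong windows (NaN if none)
    weak_per_window_rate: np.ndarray
    weak_mean_rate: float
    n_strong_windows: int
    undefined: bool = False        # no strong windows


def ds_rate(events: pd.DataFrame, seg: DeltaSegmentation, fs: float) -> RateResult:
    """Mean DS rate over strong-delta one-minute windows.

    Events falling in weak windows are summarized separately; with zero
    strong windows the mean is NaN and the result is flagged undefined.
    """
    kept = events[~events["excluded"].astype(bool)]
    win_of_event = (kept["peak_sample"].to_numpy() / fs // seg.window_s).astype(int)
    counts = np.bincount(win_of_event, minlength=seg.n_windows)[: seg.n_windows]
    per_min = counts / (seg.window_s / 60.0)
    strong = per_min[seg.strong_mask]
    weak = per_min[~seg.strong_mask]
    undefined = strong.size == 0
    if undefined:
        logger.warning("no strong-delta windows: mean DS rate undefined")
    return RateResult(
        per_window_rate=strong,
        mean_rate=float(strong.mean()) if not undefined else float("nan"),
        weak_per_window_rate=weak,
        weak_mean_rate=float(weak.mean()) if weak.size else float("nan"),
        n_strong_windows=int(strong.size),
        undefined=undefined,
    )
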