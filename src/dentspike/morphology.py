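"""Mean-waveform morphometrics.

All width metrics operate on the *mean* DS waveform, never on single events
(individual waveforms carry overlapping slow activity).  The primary width is
the distance between the two flanking upward concavities — the local maxima of
the second temporal derivative searched in [-15, -5] ms and [5, 15] ms around
the peak — measured on the waveform resampled to 4 kHz by cubic splines, so
the grid resolution is 0.25 ms.  Its key property is full invariance to
amplitude scaling and baseline offset, unlike the half-height width, which
needs a baseline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ConfigError, DegenerateInputError
from .io import WaveformMatrix

RESAMPLE_FS = 4000.0  # Hz; 0.25-ms width resolution


@dataclass
class WidthMeasurement:
    start_ms: float
    end_ms: float
    width_ms: float
    method: str                 # "second_derivative" or "half_height"
    resampled_fs: float = RESAMPLE_FS
    flagged: bool = False       # tie-break applied or limit undefined


@dataclass
class MetricSummary:
    metric_id: str
    per_group_cv: dict
    group_means: dict
    cv_of_means: float


def mean_waveform(wm: WaveformMatrix) -> np.ndarray:
    """Columnwise mean snippet across events."""
    if wm.n_events == 0:
        raise DegenerateInputError("cannot average an empty waveform matrix")
    return wm.values.mean(axis=0)


def scale_waveform(wf: np.ndarray) -> np.ndarray:
    """Z-score a mean waveform over its own window (the scaled mean waveform).

    The scaled peak amplitude is the z-scored value at the peak column.
    """
    wf = np.asarray(wf, dtype=float)
    sd = wf.std()
    if sd == 0:
        raise DegenerateInputError("constant waveform cannot be z-scored")
    return (wf - wf.mean()) / sd


def scaled_peak_amplitude(wf: np.ndarray, peak_column: int) -> float:
    return float(scale_waveform(wf)[peak_column])


def _times_ms(n: int, fs: float, window: tuple) -> np.ndarray:
    return window[0] + np.arange(n) * 1000.0 / fs


def resample_mean(wf: np.ndarray, fs: float, window: tuple,
                  target_fs: float = RESAMPLE_FS):
    """Cubic-spline interpolation of a mean waveform onto the 4-kHz grid
    spanning the same window.  Returns (resampled values, their times in ms).
    Original sample instants are knots, so their values are reproduced
    exactly."""
    wf = np.asarray(wf, dtype=float)
    t = _times_ms(wf.size, fs, window)
    step = 1000.0 / target_fs
    n_new = int(round((t[-1] - t[0]) / step)) + 1
    t_new = t[0] + np.arange(n_new) * step
    t_new = np.clip(t_new, t[0], t[-1])
    return CubicSpline(t, wf)(t_new), t_new


def second_derivative(wf: np.ndarray, dt_ms: float) -> np.ndarray:
    """Central second difference / dt^2 (ms^-2 units); endpoints copy their
    one-sided neighbours."""
    wf = np.asarray(wf, dtype=float)
    if wf.size < 3:
        raise ConfigError("second derivative needs at least 3 samples")
    d2 = np.empty_like(wf)
    d2[1:-1] = (wf[2:] - 2 * wf[1:-1] + wf[:-2]) / dt_ms**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def _argmax_toward_zero(values: np.ndarray, times: np.ndarray):
    """Index of the maximum; among exact ties, the time closest to zero wins."""
    top = np.flatnonzero(values == values.max())
    if top.size == 1:
        return int(top[0]), False
    return int(top[np.argmin(np.abs(times[top]))]), True


def _stencil_second_derivative(rs: np.ndarray, t: np.ndarray,
                               stencil_ms: float):
    """Central second difference with a widened stencil sliding on the fine
    grid: d2(t) = [w(t+h) - 2 w(t) + w(t-h)] / h^2 with h = stencil_ms.

    On spline-resampled data a one-step stencil would reproduce the spline's
    own (piecewise-linear) curvature, whose maxima snap to the original
    sample instants; a stencil as wide as the original sampling step tracks
    the waveform's curvature instead, at the fine grid's resolution.
    """
    dt = t[1] - t[0]
    s = max(1, int(round(stencil_ms / dt)))
    h = s * dt
    d2 = (rs[2 * s:] - 2 * rs[s:-s] + rs[: -2 * s]) / h**2
    return d2, t[s:-s]


def measure_width(wf: np.ndarray, fs: float, window: tuple,
                  start_band: tuple = (-15.0, -5.0),
                  end_band: tuple = (5.0, 15.0),
                  stencil_ms: float = None) -> WidthMeasurement:
    """Second-derivative width of a mean waveform.

    Start/end limits are the second-derivative maxima in the two search bands
    on the 4-kHz spline grid; width = end - start.  The second-difference
    stencil defaults to the original sample spacing (see
    :func:`_stencil_second_derivative`).
    """
    if window[0] > start_band[0] or window[1] < end_band[1]:
        raise ConfigError(
            f"waveform window {window} does not cover search bands "
            f"{start_band}/{end_band}"
        )
    rs, t = resample_mean(wf, fs, window)
    if stencil_ms is None:
        stencil_ms = 1000.0 / fs
    d2, t = _stencil_second_derivative(rs, t, stencil_ms)

    flagged = False
    limits = []
    for lo, hi in (start_band, end_band):
        band = (t >= lo) & (t <= hi)
        i, tie = _argmax_toward_zero(d2[band], t[band])
        flagged |= tie
        limits.append(float(t[band][i]))
    start, end = limits
    return WidthMeasurement(start_ms=start, end_ms=end, width_ms=end - start,
                            method="second_derivative", flagged=flagged)


def half_height_width(wf: np.ndarray, fs: float, window: tuple,
                      baseline_exclude_ms: float = 50.0) -> WidthMeasurement:
    """Width at half height of the mean waveform.

    Baseline is the mean over the window excluding ±``baseline_exclude_ms``
    around the peak; the width is the distance between the two half-height
    crossings nearest the peak on the 4-kHz grid (linearly interpolated
    between grid samples).  A missing crossing on either side leaves the
    measurement flagged with width NaN.
    """
    rs, t = resample_mean(wf, fs, window)
    outside = np.abs(t) > baseline_exclude_ms
    if not outside.any():
        raise ConfigError("window too narrow to estimate a baseline")
    baseline = rs[outside].mean()
    peak_idx = int(np.argmin(np.abs(t)))
    peak = rs[peak_idx]
    if peak <= baseline:
        return WidthMeasurement(np.nan, np.nan, np.nan, "half_height", flagged=True)
    half = (peak + baseline) / 2.0

    def crossing(side: int) -> Optional[float]:
        i = peak_idx
        while 0 < i < rs.size - 1:
            j = i + side
            if rs[j] < half <= rs[i]:
                frac = (rs[i] - half) / (rs[i] - rs[j])
                return float(t[i] + frac * (t[j] - t[i]))
            i = j
            if i <= 0 or i >= rs.size - 1:
                break
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return WidthMeasurement(np.nan, np.nan, np.nan, "half_height", flagged=True)
    return WidthMeasurement(start_ms=left, end_ms=right, width_ms=right - left,
                            method="half_height")


def cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        return np.nan
    return float(values.std(ddof=1) / m)


def cv_summary(metric_id: str, groups: dict) -> MetricSummary:
    """Per-group CVs plus the CV of the group means (spread across groups)."""
    per_group = {}
    means = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ConfigError(f"group {name!r} needs >= 2 values")
        per_group[name] = cv(vals)
        means[name] = float(vals.mean())
    mvals = np.array(list(means.values()))
    return MetricSummary(metric_id=metric_id, per_group_cv=per_group,
                         group_means=means,
                         cv_of_means=cv(mvals) if mvals.size >= 2 else np.nan)
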