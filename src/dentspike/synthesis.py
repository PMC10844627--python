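"""Seeded synthetic laminar LFP with ground-truth dentate spikes.

The generator emulates the statistical structure the detectors and
classifiers assume, not dentate-gyrus biophysics:

* **DS templates** — a Gaussian main lobe plus a smooth post-peak undershoot
  (an alpha-squared recovery, which leaves the peak position and peri-peak
  curvature untouched).  DS2 is taller and sharper with a deep undershoot;
  DS1 is wider with a shallow one, so the second-derivative widths fall on
  opposite sides of the 19-ms type boundary.
* **Laminar profile** — each template is scaled per channel by a dipole-like
  gain: positive around the hilus/granule-cell layer (the source), negative
  around a molecular-layer sink channel.  The DS1 sink sits more superficial
  (outer molecular layer) and its field spreads over more channels than DS2's
  (middle molecular layer).
* **Brain states** — a 2–4 Hz oscillation on all channels during configured
  strong-delta epochs; a faster (theta-range) oscillation during the
  remaining time, so delta-state segmentation has a real contrast to find.
* **Nuisances** — i.i.d. Gaussian broadband noise per channel, and optional
  common-mode transients (identical on every channel) standing in for
  movement/line artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import Recording, make_event_table
from . import morphology

logger = logging.getLogger(__name__)


@dataclass
class TemplateParams:
    sigma_ms: float                 # Gaussian main-lobe width parameter
    undershoot_depth: float         # fraction of peak height
    undershoot_tau_ms: float        # time of the undershoot minimum
    peak_amplitude_mv: float        # at the hilus channel
    sink_offset: int                # channels above (superficial to) the hilus
    source_spread: float            # dipole positive-lobe spread, in channels
    sink_spread: float              # dipole negative-lobe spread, in channels
    sink_gain: float = 0.8          # negative-lobe depth relative to source


#: Default template parameters.  Widths land near 22.5 ms (DS1) and 14.5 ms
#: (DS2) — both sides of the 19-ms voting boundary; DS2 is taller with a much
#: deeper post-peak undershoot; the DS1 dipole spreads over more channels.
DS1_DEFAULTS = TemplateParams(sigma_ms=6.5, undershoot_depth=0.08,
                              undershoot_tau_ms=25.0, peak_amplitude_mv=1.8,
                              sink_offset=5, source_spread=2.6, sink_spread=2.0)
DS2_DEFAULTS = TemplateParams(sigma_ms=4.2, undershoot_depth=0.30,
                              undershoot_tau_ms=15.0, peak_amplitude_mv=2.2,
                              sink_offset=3, source_spread=1.8, sink_spread=1.2)


@dataclass
class DsTemplate:
    ds_type: int
    shape: np.ndarray               # unit-peak waveform over (-half_ms, half_ms)
    fs: float
    half_ms: float
    laminar_gain: np.ndarray        # signed per-channel multiplier, 1 at hilus
    peak_amplitude_mv: float
    sink_channel_index: int         # depth index of the configured sink
    params: TemplateParams = None

    @property
    def peak_index(self) -> int:
        return int(round(self.half_ms * self.fs / 1000.0))


def _template_shape(p: TemplateParams, fs: float, half_ms: float) -> np.ndarray:
    t = (np.arange(2 * round(half_ms * fs / 1000.0) + 1) * 1000.0 / fs) - half_ms
    main = np.exp(-0.5 * (t / p.sigma_ms) ** 2)
    # alpha-squared undershoot: zero value, slope and curvature at t=0, so the
    # unit peak stays exactly at t=0 and peri-peak concavity is unchanged
    u = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / p.undershoot_tau_ms
    u[pos] = -p.undershoot_depth * x**2 * np.exp(2.0 * (1.0 - x))
    shape = main + u
    return shape / shape.max()


def _laminar_gain(p: TemplateParams, n_channels: int, hilus_index: int) -> np.ndarray:
    idx = np.arange(n_channels, dtype=float)
    sink_index = hilus_index - p.sink_offset
    if sink_index < 1:
        raise ConfigError("sink channel falls off the superficial end of the probe")
    source = np.exp(-0.5 * ((idx - hilus_index) / p.source_spread) ** 2)
    sink = np.exp(-0.5 * ((idx - sink_index) / p.sink_spread) ** 2)
    g = source - p.sink_gain * sink
    return g / g[hilus_index]


def make_ds_template(ds_type: int, fs: float = 1000.0, half_ms: float = 100.0,
                     n_channels: int = 16, hilus_index: int = 12,
                     params: TemplateParams = None) -> DsTemplate:
    """Build a DS1 or DS2 template and verify its measured width lands on the
    correct side of the 19-ms boundary for the requested type."""
    if ds_type not in (1, 2):
        raise ConfigError(f"ds_type must be 1 or 2, got {ds_type}")
    p = params or (DS1_DEFAULTS if ds_type == 1 else DS2_DEFAULTS)
    shape = _template_shape(p, fs, half_ms)
    width = morphology.measure_width(shape, fs, (-half_ms, half_ms)).width_ms
    if (ds_type == 1) != (width > 19.0):
        raise ConfigError(
            f"DS{ds_type} template parameters give width {width:.2f} ms, on the "
            f"wrong side of the 19-ms boundary"
        )
    gain = _laminar_gain(p, n_channels, hilus_index)
    return DsTemplate(ds_type=ds_type, shape=shape, fs=fs, half_ms=half_ms,
                      laminar_gain=gain,
                      peak_amplitude_mv=p.peak_amplitude_mv,
                      sink_channel_index=hilus_index - p.sink_offset,
                      params=p)


@dataclass
class ArtifactSpec:
    times_s: Sequence[float]
    amplitude_mv: float = 8.0
    duration_ms: float = 10.0
    polarity: int = 1


@dataclass
class SynthConfig:
    fs: float = 1000.0
    duration_s: float = 600.0
    n_channels: int = 16
    hilus_index: int = 12                  # depth index (0 = most superficial)
    n_ds1: int = 100
    n_ds2: int = 100
    ds1_params: TemplateParams = None
    ds2_params: TemplateParams = None
    strong_epochs: Optional[List[Tuple[float, float]]] = None  # None -> whole recording
    delta_freq_hz: float = 3.0
    delta_amp_mv: float = 0.2
    theta_freq_hz: float = 6.5             # fills weak-delta epochs
    theta_amp_mv: float = 0.12
    noise_sd_mv: float = 0.1
    artifacts: Optional[ArtifactSpec] = None
    events_in_strong_only: bool = True
    amp_jitter: float = 0.05               # lognormal-ish relative amplitude sd
    min_gap_ms: float = 80.0               # ground-truth inter-event spacing
    seed: int = 0

    def __post_init__(self):
        if self.n_ds1 < 0 or self.n_ds2 < 0:
            raise ConfigError("event counts must be >= 0")
        if self.strong_epochs is not None:
            for a, b in self.strong_epochs:
                if not (0 <= a < b <= self.duration_s):
                    raise ConfigError(f"epoch ({a}, {b}) outside recording")
        if self.min_gap_ms < 50.0:
            raise ConfigError("ground-truth spacing must be >= 50 ms")


def _place_event_times(cfg: SynthConfig, rng: np.random.Generator,
                       n_events: int, margin_s: float) -> np.ndarray:
    """Draw event times inside the allowed epochs with the configured minimum
    spacing (greedy accept over a shuffled millisecond grid)."""
    epochs = cfg.strong_epochs if (cfg.events_in_strong_only and cfg.strong_epochs) \
        else [(0.0, cfg.duration_s)]
    candidates = []
    for a, b in epochs:
        lo, hi = a + margin_s, b - margin_s
        if hi > lo:
            candidates.append(np.arange(lo, hi, 0.001))
    if not candidates:
        raise ConfigError("no room for events inside the allowed epochs")
    grid = np.concatenate(candidates)
    rng.shuffle(grid)
    gap = cfg.min_gap_ms / 1000.0
    chosen: List[float] = []
    for t in grid:
        if all(abs(t - c) >= gap for c in chosen):
            chosen.append(t)
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events:
        raise ConfigError(
            f"could only place {len(chosen)} of {n_events} events under the "
            f"{cfg.min_gap_ms}-ms spacing constraint"
        )
    return np.sort(np.array(chosen))


def synthesize_recording(cfg: SynthConfig):
    """Generate a seeded laminar recording plus its ground-truth event table.

    Returns ``(Recording, truth)`` where ``truth`` is an event table with an
    extra ``true_type`` column; ``peak_amplitude_mv`` holds the noiseless
    planted hilus amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    data = np.zeros((cfg.n_channels, n))

    tpl1 = make_ds_template(1, cfg.fs, n_channels=cfg.n_channels,
                            hilus_index=cfg.hilus_index, params=cfg.ds1_params)
    tpl2 = make_ds_template(2, cfg.fs, n_channels=cfg.n_channels,
                            hilus_index=cfg.hilus_index, params=cfg.ds2_params)

    n_total = cfg.n_ds1 + cfg.n_ds2
    margin = tpl1.half_ms / 1000.0 + 0.001
    times = _place_event_times(cfg, rng, n_total, margin)
    types = np.array([1] * cfg.n_ds1 + [2] * cfg.n_ds2)
    rng.shuffle(types)

    peak_samples = np.round(times * cfg.fs).astype(int)
    amps = np.empty(n_total)
    for i, (p, typ) in enumerate(zip(peak_samples, types)):
        tpl = tpl1 if typ == 1 else tpl2
        amp = tpl.peak_amplitude_mv * float(np.exp(rng.normal(0.0, cfg.amp_jitter)))
        amps[i] = amp
        lo = p - tpl.peak_index
        hi = lo + tpl.shape.size
        data[:, lo:hi] += amp * np.outer(tpl.laminar_gain, tpl.shape)

    # brain-state oscillations: delta in strong epochs, theta elsewhere
    t = np.arange(n) / cfg.fs
    strong = np.zeros(n, dtype=bool)
    for a, b in (cfg.strong_epochs or [(0.0, cfg.duration_s)]):
        strong[int(a * cfg.fs): int(b * cfg.fs)] = True
    phase_d, phase_t = rng.uniform(0, 2 * np.pi, size=2)
    osc = np.where(
        strong,
        cfg.delta_amp_mv * np.sin(2 * np.pi * cfg.delta_freq_hz * t + phase_d),
        cfg.theta_amp_mv * np.sin(2 * np.pi * cfg.theta_freq_hz * t + phase_t),
    )
    data += osc[None, :]

    if cfg.noise_sd_mv > 0:
        data += rng.normal(0.0, cfg.noise_sd_mv, size=data.shape)

    rec = Recording(samples=data, fs=cfg.fs,
                    channel_order=list(range(cfg.n_channels)),
                    meta={"synthetic": True, "seed": cfg.seed})
    if cfg.artifacts is not None:
        rec = inject_artifacts(rec, cfg.artifacts)

    order = np.argsort(peak_samples)
    truth = make_event_table(peak_samples[order], cfg.hilus_index, amps[order])
    truth["true_type"] = types[order]
    return rec, truth


def inject_artifacts(rec: Recording, spec: ArtifactSpec) -> Recording:
    """Add an identical (common-mode) transient to every channel at each
    listed time, so reference subtraction can cancel it exactly."""
    data = rec.samples.copy()
    dur = int(round(spec.duration_ms * rec.fs / 1000.0))
    pulse = spec.polarity * spec.amplitude_mv * np.hanning(max(dur, 3))
    for t0 in spec.times_s:
        start = int(round(t0 * rec.fs))
        if start < 0 or start + pulse.size > rec.n_samples:
            raise ConfigError(f"artifact at {t0}s falls outside the recording")
        data[:, start: start + pulse.size] += pulse[None, :]
    return Recording(samples=data, fs=rec.fs, channel_order=rec.channel_order,
                     channel_spacing=rec.channel_spacing,
                     meta={**rec.meta, "artifacts_injected": len(list(spec.times_s))})
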