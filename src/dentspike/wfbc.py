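"""Waveform-based DS classification (WFbC) — single-channel typing.

Where the CSD method needs a laminar probe, WFbC types dentate spikes from
one recording site alone.  The pipeline:

1. **Features** — each event is its raw-LFP snippet from -15 to +15 ms
   around the peak (31 samples at 1 kHz).  No standardization and no
   dimensionality reduction: the raw amplitudes carry the type information.
2. **Clustering with artifact rejection** — a two-component full-covariance
   Gaussian mixture (best of 20 seeds).  Any cluster holding less than 5% of
   the *originally* detected events is treated as a bundled artifact group:
   its events are rejected and the mixture refit on the remainder, iterating
   until both clusters hold between 5% and 95%.
3. **Type assignment** — the cluster whose mean waveform has the lower sum
   over 10–50 ms after the peak (the stronger post-peak negativity) is DS2.
4. **Single-type check** (optional) — the dissimilarity index (DI) compares
   the clusters' mean waveforms through their min-max-scaled second
   derivatives over a 20-ms peri-peak window; DI <= 0.06 means the mixture
   split one population in two, and a three-criterion width vote assigns the
   single type to every event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import ConfigError, DegenerateInputError
from .io import WaveformMatrix
from . import morphology
from .csd import ClusterAssignment, gmm_cluster, RECOMMENDED_MIN_EVENTS

logger = logging.getLogger(__name__)


@dataclass
class WfbcConfig:
    feature_window_ms: tuple = (-15.0, 15.0)
    artifact_fraction: float = 0.05
    postpeak_window_ms: tuple = (10.0, 50.0)
    di_window_ms: float = 20.0          # full width, centered at the peak
    di_threshold: float = 0.06          # 0.07 in stubborn borderline cases
    vote_width_ms: float = 19.0
    vote_start_ms: float = -9.5
    vote_end_ms: float = 9.5
    n_seeds: int = 20
    seed_base: int = 0
    check_single_type: bool = True

    def __post_init__(self):
        if not (0 < self.artifact_fraction < 0.5):
            raise ConfigError("artifact_fraction must be in (0, 0.5)")
        if self.di_threshold <= 0:
            raise ConfigError("di_threshold must be positive")


@dataclass
class DissimilarityResult:
    di: float
    same_type: bool
    scaled_d2_a: np.ndarray
    scaled_d2_b: np.ndarray
    flagged: bool = False     # a flat second derivative made scaling degenerate


def _resample_rows(values: np.ndarray, t_src: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    return CubicSpline(t_src, values, axis=1)(t_dst)


def extract_features(wm: WaveformMatrix, cfg: WfbcConfig = None) -> np.ndarray:
    """Event x 31 raw-amplitude feature matrix over (-15, 15) ms at 1 kHz.

    Snippets recorded at another rate are spline-resampled onto the 1-kHz
    grid (logged); the peak sample itself is a grid point either way.
    """
    cfg = cfg or WfbcConfig()
    lo, hi = cfg.feature_window_ms
    if wm.window[0] > lo or wm.window[1] < hi:
        raise ConfigError(
            f"waveform window {wm.window} does not cover the feature window "
            f"({lo}, {hi}) ms"
        )
    t_feat = lo + np.arange(int(round(hi - lo)) + 1)  # 1-kHz grid, 31 samples
    if wm.fs == 1000.0:
        cols = [wm.column_of(t) for t in t_feat]
        return wm.values[:, cols]
    logger.info("resampling %g-Hz snippets to the 1-kHz feature grid", wm.fs)
    return _resample_rows(wm.values, wm.times_ms, t_feat)


def cluster_with_artifact_rejection(features: np.ndarray, cfg: WfbcConfig = None,
                                    seeds: Sequence[int] = None):
    """GMM clustering with iterative rejection of sub-5% artifact clusters.

    The 5% floor is measured against the *original* event count throughout.
    Returns ``(ClusterAssignment over surviving events, surviving row index,
    rejected row index)``.
    """
    cfg = cfg or WfbcConfig()
    X = np.asarray(features, dtype=float)
    n0 = X.shape[0]
    if n0 < 20:
        raise ConfigError(f"need at least 20 events, got {n0}")
    if seeds is None:
        seeds = range(cfg.seed_base, cfg.seed_base + cfg.n_seeds)
    seeds = list(seeds)

    active = np.arange(n0)
    rejected = []
    while True:
        if active.size < 4:
            raise ConfigError("no stable partition: artifact rejection "
                              "exhausted the events")
        assign = gmm_cluster(X[active], k=2, seeds=seeds)
        counts = np.bincount(assign.labels, minlength=2)
        fracs = counts / n0
        if fracs.min() >= cfg.artifact_fraction:
            return assign, active, np.array(rejected, dtype=int)
        small = int(np.argmin(counts))
        drop = active[assign.labels == small]
        logger.info("artifact-cluster rejection: dropping %d events "
                    "(%.1f%% of the original %d)", drop.size,
                    100 * fracs[small], n0)
        rejected.extend(drop.tolist())
        active = active[assign.labels != small]


def assign_types_by_postpeak(mean_wf_a: np.ndarray, mean_wf_b: np.ndarray,
                             fs: float, window: tuple,
                             cfg: WfbcConfig = None):
    """Lower post-peak (10–50 ms) sum -> DS2.  Returns (type_map, flagged)."""
    cfg = cfg or WfbcConfig()
    lo, hi = cfg.postpeak_window_ms
    if window[1] < hi:
        raise ConfigError(f"mean waveforms must cover +{hi} ms, window is {window}")
    t = window[0] + np.arange(len(mean_wf_a)) * 1000.0 / fs
    sel = (t > lo) & (t <= hi)
    sums = [float(np.sum(np.asarray(w)[sel])) for w in (mean_wf_a, mean_wf_b)]
    flagged = False
    if sums[0] == sums[1]:
        # measure-zero tie: the sharper peak (larger |d2| at t=0) is DS2
        flagged = True
        dt = 1000.0 / fs
        i0 = int(np.argmin(np.abs(t)))
        sharp = [abs(float(morphology.second_derivative(np.asarray(w), dt)[i0]))
                 for w in (mean_wf_a, mean_wf_b)]
        ds2 = int(np.argmax(sharp))
        logger.warning("post-peak sums tied; falling back to peak sharpness")
    else:
        ds2 = int(np.argmin(sums))
    return {ds2: 2, 1 - ds2: 1}, flagged


def _scaled_second_derivative(wf: np.ndarray, fs: float, window: tuple,
                              half_ms: float):
    """Min-max-scaled second derivative over the DI window.  Returns
    (scaled values, degenerate flag)."""
    wf = np.asarray(wf, dtype=float)
    t = window[0] + np.arange(wf.size) * 1000.0 / fs
    d2 = morphology.second_derivative(wf, dt_ms=1000.0 / fs)
    sel = (t >= -half_ms) & (t <= half_ms)
    d2w = d2[sel]
    span = d2w.max() - d2w.min()
    if span == 0:
        return np.full(d2w.size, 0.5), True
    return (d2w - d2w.min()) / span, False


def dissimilarity_index(mean_wf_a: np.ndarray, mean_wf_b: np.ndarray,
                        fs: float, window: tuple,
                        cfg: WfbcConfig = None,
                        threshold: float = None) -> DissimilarityResult:
    """Mean absolute difference of the min-max-scaled second derivatives over
    the peri-peak DI window; DI <= threshold means a single DS type."""
    cfg = cfg or WfbcConfig()
    if threshold is None:
        threshold = cfg.di_threshold
    half = cfg.di_window_ms / 2.0
    if window[0] > -half or window[1] < half:
        raise ConfigError(f"waveforms must cover ±{half} ms, window is {window}")
    a, fa = _scaled_second_derivative(mean_wf_a, fs, window, half)
    b, fb = _scaled_second_derivative(mean_wf_b, fs, window, half)
    di = float(np.mean(np.abs(a - b)))
    return DissimilarityResult(di=di, same_type=di <= threshold,
                               scaled_d2_a=a, scaled_d2_b=b,
                               flagged=fa or fb)


def single_type_vote(width: morphology.WidthMeasurement,
                     cfg: WfbcConfig = None) -> int:
    """Three-criterion majority vote on the merged group's width metrics.

    Votes for type 1: width over 19 ms; start limit before -9.5 ms; end limit
    after +9.5 ms.  Two of three decide.
    """
    cfg = cfg or WfbcConfig()
    votes = [
        width.width_ms > cfg.vote_width_ms,
        width.start_ms < cfg.vote_start_ms,
        width.end_ms > cfg.vote_end_ms,
    ]
    return 1 if sum(votes) >= 2 else 2


class WaveformClassifier(BaseEstimator, ClusterMixin):
    """Single-channel waveform DS classifier (sklearn-style estimator).

    Fit on an (events x samples) matrix of peak-aligned raw-LFP snippets
    spanning ``window`` ms around the peak at ``fs`` Hz; the window must
    cover -15 to +50 ms.  After fitting:

    ``labels_``
        DS type per event in {1, 2}; artifact-cluster-rejected events get -1.
    ``posteriors_``
        Max GMM membership probability (NaN for rejected events).
    ``merged_single_type_``
        True when the dissimilarity check collapsed the two clusters.
    """

    def __init__(self, fs: float = 1000.0, window: tuple = (-100.0, 100.0),
                 artifact_fraction: float = 0.05, di_threshold: float = 0.06,
                 n_seeds: int = 20, seed_base: int = 0,
                 check_single_type: bool = True):
        self.fs = fs
        self.window = window
        self.artifact_fraction = artifact_fraction
        self.di_threshold = di_threshold
        self.n_seeds = n_seeds
        self.seed_base = seed_base
        self.check_single_type = check_single_type

    def _config(self) -> WfbcConfig:
        return WfbcConfig(artifact_fraction=self.artifact_fraction,
                          di_threshold=self.di_threshold,
                          n_seeds=self.n_seeds, seed_base=self.seed_base,
                          check_single_type=self.check_single_type)

    def fit(self, X, y=None):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        wm = WaveformMatrix(values=X, window=self.window, fs=self.fs,
                            event_ids=np.arange(X.shape[0]))
        if self.window[1] < cfg.postpeak_window_ms[1]:
            raise ConfigError(
                f"window {self.window} must reach +{cfg.postpeak_window_ms[1]} ms "
                f"for post-peak type assignment"
            )
        n = wm.n_events
        if n < RECOMMENDED_MIN_EVENTS:
            logger.warning("WFbC fitted on %d events; more than %d are "
                           "recommended", n, RECOMMENDED_MIN_EVENTS)

        feats = extract_features(wm, cfg)
        assign, active, rejected = cluster_with_artifact_rejection(feats, cfg)

        mean_wfs = [X[active][assign.labels == c].mean(axis=0) for c in (0, 1)]
        type_map, tie_flag = assign_types_by_postpeak(
            mean_wfs[0], mean_wfs[1], self.fs, self.window, cfg)

        labels = np.full(n, -1, dtype=int)
        posts = np.full(n, np.nan)
        labels[active] = [type_map[c] for c in assign.labels]
        posts[active] = assign.posteriors

        self.di_ = None
        self.merged_single_type_ = False
        self.vote_ = None
        if self.check_single_type:
            di = dissimilarity_index(mean_wfs[0], mean_wfs[1], self.fs,
                                     self.window, cfg)
            self.di_ = di.di
            if di.same_type:
                merged_mean = X[active].mean(axis=0)
                width = morphology.measure_width(merged_mean, self.fs, self.window)
                single = single_type_vote(width, cfg)
                labels[active] = single
                self.merged_single_type_ = True
                self.vote_ = {"width_ms": width.width_ms,
                              "start_ms": width.start_ms,
                              "end_ms": width.end_ms,
                              "type": int(single)}
                logger.info("single-type check merged the clusters: DI=%.4f, "
                            "voted type %d", di.di, single)

        self.labels_ = labels
        self.posteriors_ = posts
        self.rejected_mask_ = labels == -1
        self.type_map_ = type_map
        self.postpeak_tie_ = tie_flag
        counts = np.bincount(assign.labels, minlength=2)
        self.cluster_fractions_ = counts / n
        self.mean_waveforms_ = np.array(mean_wfs)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def classify_wfbc(wm: WaveformMatrix, events: pd.DataFrame = None,
                  cfg: WfbcConfig = None):
    """Functional wrapper: label a waveform matrix (and, when given, the
    matching event table's ``label_wfbc``/``posterior`` columns).

    Returns ``(labels or updated events, report dict)``.
    """
    cfg = cfg or WfbcConfig()
    clf = WaveformClassifier(fs=wm.fs, window=wm.window,
                             artifact_fraction=cfg.artifact_fraction,
                             di_threshold=cfg.di_threshold,
                             n_seeds=cfg.n_seeds, seed_base=cfg.seed_base,
                             check_single_type=cfg.check_single_type)
    clf.fit(wm.values)
    report = {
        "cluster_fractions": clf.cluster_fractions_.tolist(),
        "di": clf.di_,
        "merged_single_type": clf.merged_single_type_,
        "vote": clf.vote_,
        "n_events": int(wm.n_events),
        "n_rejected": int(clf.rejected_mask_.sum()),
    }
    if events is None:
        return clf.labels_, report
    events = events.copy()
    id_to_label = dict(zip(wm.event_ids, clf.labels_))
    id_to_post = dict(zip(wm.event_ids, clf.posteriors_))
    for idx, ev_id in zip(events.index, events["event_id"]):
        if ev_id in id_to_label:
            lab = id_to_label[ev_id]
            if lab == -1:
                events.loc[idx, "excluded"] = True
                events.loc[idx, "excluded_reason"] = "artifact_cluster"
            else:
                events.loc[idx, "label_wfbc"] = lab
                events.loc[idx, "posterior"] = id_to_post[ev_id]
    events["label_wfbc"] = events["label_wfbc"].astype("Int64")
    return events, report
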