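"""Scoring and validation experiments for the DS classifiers.

Accuracy here means the fraction of events labelled identically by the
method under test and the reference (ground-truth generation labels on
synthetic data, or the CSD-based method on real recordings).  The
experiments probe how WFbC degrades with class imbalance, event count and
additive noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix

from .exceptions import ConfigError
from .detection import DetectionConfig, detect_dentate_spikes
from .io import Recording, WaveformMatrix
from .wfbc import WaveformClassifier, WfbcConfig

logger = logging.getLogger(__name__)


@dataclass
class ClassificationReport:
    confusion: np.ndarray           # 2x2 counts, rows = true {1,2}, cols = predicted
    accuracy: float
    precision: dict                 # per type
    recall: dict
    n_events: int
    ds2_proportion: float

    @property
    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized confusion; the main diagonal holds the recalls."""
        sums = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.confusion / sums, np.nan)


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    pearson_r: float
    wald_p_vs_1: float              # two-sided t-test of slope == 1


def score(reference, predicted) -> ClassificationReport:
    """Confusion counts, accuracy and per-type precision/recall for labels in
    {1, 2}."""
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if ref.shape != pred.shape:
        raise ConfigError("reference and prediction lengths differ")
    if not (np.isin(ref, (1, 2)).all() and np.isin(pred, (1, 2)).all()):
        raise ConfigError("labels must be in {1, 2}")
    cm = confusion_matrix(ref, pred, labels=[1, 2])
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    precision, recall = {}, {}
    for i, typ in enumerate((1, 2)):
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        precision[typ] = float(cm[i, i] / col) if col else np.nan
        recall[typ] = float(cm[i, i] / row) if row else np.nan
    return ClassificationReport(confusion=cm, accuracy=accuracy,
                                precision=precision, recall=recall,
                                n_events=int(total),
                                ds2_proportion=float((ref == 2).mean()))


def regression_vs_identity(x, y) -> RegressionSummary:
    """OLS fit of y on x, Pearson r, and the Wald t-test of slope == 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ConfigError("need at least 3 points")
    if x.std() == 0:
        raise ConfigError("x has zero variance")
    res = stats.linregress(x, y)
    if res.stderr == 0:
        p = 1.0 if res.slope == 1.0 else 0.0
    else:
        t = (res.slope - 1.0) / res.stderr
        p = float(2 * stats.t.sf(abs(t), x.size - 2))
    return RegressionSummary(slope=float(res.slope), intercept=float(res.intercept),
                             pearson_r=float(res.rvalue), wald_p_vs_1=p)


def _classify_pool(X: np.ndarray, fs: float, window: tuple, seed_base: int,
                   n_seeds: int, check_single_type: bool = True):
    clf = WaveformClassifier(fs=fs, window=window, seed_base=seed_base,
                             n_seeds=n_seeds,
                             check_single_type=check_single_type)
    # the small-pool warning would fire once per draw inside experiments
    wfbc_logger = logging.getLogger("dentspike.wfbc")
    level = wfbc_logger.level
    wfbc_logger.setLevel(logging.ERROR)
    try:
        clf.fit(X)
    finally:
        wfbc_logger.setLevel(level)
    return clf


def subsample_experiment(wm: WaveformMatrix, true_labels,
                         ds2_proportions: Sequence[float] = tuple(np.arange(0.1, 0.95, 0.1)),
                         totals: Sequence[int] = (200, 500, 1000),
                         rounds: int = 200, seed: int = 0,
                         n_seeds_gmm: int = 20) -> pd.DataFrame:
    """WFbC accuracy versus DS2 proportion and event count.

    For each (proportion, total) cell, ``rounds`` independent draws without
    replacement are classified from scratch; the table reports the median and
    IQR of accuracy against the pool labels, the fraction of rounds merged to
    a single cluster by the DI check, and the chance level max(p, 1-p).
    """
    true_labels = np.asarray(true_labels, dtype=int)
    idx1 = np.flatnonzero(true_labels == 1)
    idx2 = np.flatnonzero(true_labels == 2)
    records = []
    for p2 in ds2_proportions:
        for total in totals:
            n2 = int(round(p2 * total))
            n1 = total - n2
            if n1 > idx1.size or n2 > idx2.size:
                logger.warning("skipping proportion %.2f, total %d: pool too "
                               "small", p2, total)
                continue
            accs, merged = [], 0
            for r in range(rounds):
                rng = np.random.default_rng(seed + r)
                pick = np.concatenate([
                    rng.choice(idx1, size=n1, replace=False),
                    rng.choice(idx2, size=n2, replace=False),
                ])
                clf = _classify_pool(wm.values[pick], wm.fs, wm.window,
                                     seed_base=seed + r, n_seeds=n_seeds_gmm)
                ok = ~clf.rejected_mask_
                rep = score(true_labels[pick][ok], clf.labels_[ok])
                accs.append(rep.accuracy)
                merged += int(clf.merged_single_type_)
            q1, med, q3 = np.percentile(accs, [25, 50, 75])
            records.append({
                "ds2_proportion": float(p2), "total": int(total),
                "median_accuracy": float(med), "iqr_low": float(q1),
                "iqr_high": float(q3),
                "single_cluster_rate": merged / rounds,
                "chance": float(max(p2, 1 - p2)),
                "rounds": rounds,
            })
    return pd.DataFrame.from_records(records)


def noise_tolerance_experiment(wm: WaveformMatrix, true_labels,
                               sd_grid_mv: Sequence[float] = tuple(np.arange(0, 1.05, 0.1)),
                               seed: int = 0, n_repeats: int = 5,
                               n_seeds_gmm: int = 20,
                               n_per_type: int = None) -> pd.DataFrame:
    """WFbC accuracy under additive Gaussian waveform noise.

    The pool is balanced (equal DS1/DS2 counts by subsampling) before noise
    of each standard deviation is added to every waveform sample; accuracy is
    reported as mean ± sd over repeats.
    """
    true_labels = np.asarray(true_labels, dtype=int)
    idx1 = np.flatnonzero(true_labels == 1)
    idx2 = np.flatnonzero(true_labels == 2)
    n_side = min(idx1.size, idx2.size) if n_per_type is None \
        else min(n_per_type, idx1.size, idx2.size)
    rng0 = np.random.default_rng(seed)
    keep = np.concatenate([rng0.choice(idx1, n_side, replace=False),
                           rng0.choice(idx2, n_side, replace=False)])
    X0 = wm.values[keep]
    labels0 = true_labels[keep]

    records = []
    for sd in sd_grid_mv:
        accs, merged = [], 0
        for r in range(n_repeats):
            rng = np.random.default_rng(seed + 1000 * r + 1)
            X = X0 + (rng.normal(0.0, sd, size=X0.shape) if sd > 0 else 0.0)
            clf = _classify_pool(X, wm.fs, wm.window, seed_base=seed + r,
                                 n_seeds=n_seeds_gmm)
            ok = ~clf.rejected_mask_
            rep = score(labels0[ok], clf.labels_[ok])
            accs.append(rep.accuracy)
            merged += int(clf.merged_single_type_)
        records.append({
            "noise_sd_mv": float(sd),
            "mean_accuracy": float(np.mean(accs)),
            "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "single_cluster_rate": merged / n_repeats,
        })
    return pd.DataFrame.from_records(records)


def detection_noise_experiment(rec: Recording, channel,
                               sd_grid_mv: Sequence[float],
                               cfg: DetectionConfig = None, seed: int = 0,
                               n_repeats: int = 3) -> pd.DataFrame:
    """Detected event count as LFP noise grows: added noise inflates the
    median-based threshold, so counts fall toward zero as the noise scale
    approaches the mean peak amplitude."""
    cfg = cfg or DetectionConfig()
    records = []
    base = rec.get_channel(channel)
    ch_idx = rec.channel_index(channel)
    for sd in sd_grid_mv:
        counts = []
        for r in range(n_repeats):
            rng = np.random.default_rng(seed + 1000 * r + 7)
            noisy = rec.samples.copy()
            if sd > 0:
                noisy[ch_idx] = base + rng.normal(0.0, sd, size=base.size)
            noisy_rec = Recording(samples=noisy, fs=rec.fs,
                                  channel_order=rec.channel_order,
                                  channel_spacing=rec.channel_spacing)
            events = detect_dentate_spikes(noisy_rec, channel, cfg)
            counts.append(int((~events["excluded"]).sum()))
        records.append({
            "noise_sd_mv": float(sd),
            "median_count": float(np.median(counts)),
            "counts": counts,
        })
    return pd.DataFrame.from_records(records)
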