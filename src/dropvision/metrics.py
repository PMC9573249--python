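"""Quantification and evaluation metrics for droplet dPCR runs.

Covers the confusion-matrix scores used to validate classification
(accuracy, sensitivity, specificity), the Poisson estimator that turns a
positive-droplet fraction into a template concentration
(λ = −ln(1 − p), concentration = λ / droplet volume), point matching of
detections against ground truth, and the concentration-gradient report
(per-level replicate scatter and the Pearson correlation of measured
versus true positive fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "QuantResult",
    "confusion_metrics",
    "quantify",
    "gradient_report",
    "match_points",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_metrics(c: ConfusionCounts):
    """(accuracy, sensitivity, specificity).

    accuracy = (TP+TN)/(TP+FN+FP+TN), sensitivity = TP/(TP+FN),
    specificity = TN/(FP+TN). A metric whose denominator is zero is
    returned as ``None`` (undefined), never silently as 0.
    """
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = c.tn / (c.fp + c.tn) if (c.fp + c.tn) > 0 else None
    return accuracy, sensitivity, specificity


@dataclass
class QuantResult:
    n_pos: int
    n_neg: int
    positive_fraction: float
    lam: float  # mean template copies per droplet
    concentration: float  # copies per picoliter
    droplet_volume_pl: float

    @property
    def copies_per_ul(self) -> float:
        return self.concentration * 1e6


def quantify(n_pos: int, n_neg: int, droplet_volume_pl: float = 24.0) -> QuantResult:
    """Poisson absolute quantification from positive/negative counts.

    With occupancy Poisson(λ) per droplet, the fraction of empty
    (negative) droplets is e^{−λ}, so λ = −ln(1 − p) for positive
    fraction p, and concentration = λ / droplet volume. The default
    droplet volume is 24 pL. A saturated sample (no negatives) has no
    finite λ and raises.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("no droplets to quantify")
    if droplet_volume_pl <= 0:
        raise ValueError("droplet volume must be positive")
    if n_neg == 0:
        raise ValueError("all droplets positive: Poisson estimate saturates "
                         "(lambda undefined); dilute the sample")
    p = n_pos / total
    lam = -math.log(1.0 - p)
    return QuantResult(n_pos=n_pos, n_neg=n_neg, positive_fraction=p,
                       lam=lam, concentration=lam / droplet_volume_pl,
                       droplet_volume_pl=droplet_volume_pl)


def gradient_report(per_sample):
    """Concentration-gradient summary.

    ``per_sample`` is a sequence of (true_fraction, measured_fraction)
    pairs, replicates included. Replicates are grouped by their true
    level; the report returns the Pearson correlation of the per-level
    mean measured fraction against the true fraction, and a DataFrame
    with per-level mean and standard deviation of the replicate
    measurements.
    """
    pairs = [(float(t), float(m)) for t, m in per_sample]
    if len(pairs) < 2:
        raise ValueError("need at least two samples")
    frame = pd.DataFrame(pairs, columns=["true_fraction", "measured_fraction"])
    levels = (frame.groupby("true_fraction", sort=True)["measured_fraction"]
              .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=0)),
                   n_replicates="count").reset_index())
    truth = levels["true_fraction"].to_numpy()
    meas = levels["mean"].to_numpy()
    if truth.size < 2 or np.std(truth) == 0 or np.std(meas) == 0:
        raise ValueError("Pearson correlation undefined: a variable has "
                         "zero variance")
    r = float(stats.pearsonr(truth, meas).statistic)
    return r, levels


def match_points(truth_xy: np.ndarray, detected_xy: np.ndarray,
                 max_dist: float):
    """Greedy nearest-neighbor matching of detections to ground truth.

    Candidate pairs within ``max_dist`` are accepted in order of
    increasing distance, each point used at most once. Returns
    ``(pairs, unmatched_truth, unmatched_detected)`` as index arrays.
    """
    truth_xy = np.asarray(truth_xy, dtype=np.float64).reshape(-1, 2)
    detected_xy = np.asarray(detected_xy, dtype=np.float64).reshape(-1, 2)
    if truth_xy.size == 0 or detected_xy.size == 0:
        return (np.empty((0, 2), dtype=int),
                np.arange(len(truth_xy)), np.arange(len(detected_xy)))
    tree = cKDTree(truth_xy)
    cand = []
    for di, p in enumerate(detected_xy):
        for ti in tree.query_ball_point(p, max_dist):
            cand.append((float(np.hypot(*(truth_xy[ti] - p))), ti, di))
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _, ti, di in cand:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((ti, di))
    pairs_arr = (np.asarray(pairs, dtype=int) if pairs
                 else np.empty((0, 2), dtype=int))
    un_t = np.array([i for i in range(len(truth_xy)) if i not in used_t], dtype=int)
    un_d = np.array([i for i in range(len(detected_xy)) if i not in used_d], dtype=int)
    return pairs_arr, un_t, un_d
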