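"""Positive/negative droplet classification by 1-D two-means clustering.

For scalar signals the optimal two-cluster k-means partition is a
threshold on the sorted values, so Lloyd iteration from a deterministic
initialization (the signal minimum and maximum as starting centers)
converges to the same answer as an exhaustive threshold scan while
remaining reproducible. The cluster with the larger center is labeled
positive. A separation gate flags images whose two cluster centers are
too close to trust (e.g. single-population fields), so they can be
excluded from pooled quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterResult", "kmeans_1d", "quality_gate"]


@dataclass
class ClusterResult:
    labels: np.ndarray  # array of "positive"/"negative"
    center_neg: float
    center_pos: float
    separation: float  # center_pos - center_neg
    within_sd: float  # pooled within-cluster standard deviation
    n_iter: int
    quality_ok: bool | None = None

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == "positive"))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == "negative"))


def kmeans_1d(signals, seed: int = 0, n_restarts: int = 0,
              max_iter: int = 200) -> ClusterResult:
    """Two-means clustering of 1-D signals.

    Deterministic min/max initialization; ``n_restarts`` adds seeded
    random restarts (pairs of distinct data points as initial centers)
    and keeps the lowest within-cluster sum of squares — rarely needed
    in 1-D but retained for parity with generic k-means practice.
    Points equidistant from both centers go to the negative cluster.
    Raises ``ValueError`` for fewer than two distinct signal values.
    """
    x = np.asarray(signals, dtype=np.float64).ravel()
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("k-means needs at least two distinct signal values")

    def _lloyd(c_lo: float, c_hi: float):
        assign = None
        for it in range(1, max_iter + 1):
            mid = (c_lo + c_hi) / 2.0
            new_assign = x > mid  # True -> high cluster; ties -> low/negative
            if not new_assign.any() or new_assign.all():
                # One empty cluster: snap centers back to the extremes.
                new_assign = x > (uniq[0] + uniq[-1]) / 2.0
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            c_lo = float(x[~assign].mean())
            c_hi = float(x[assign].mean())
        ss = float(np.sum((x[~assign] - c_lo) ** 2)
                   + np.sum((x[assign] - c_hi) ** 2))
        return assign, c_lo, c_hi, it, ss

    best = _lloyd(float(uniq[0]), float(uniq[-1]))
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            c0, c1 = rng.choice(uniq, size=2, replace=False)
            cand = _lloyd(float(min(c0, c1)), float(max(c0, c1)))
            if cand[4] < best[4]:
                best = cand
    assign, c_lo, c_hi, n_iter, ss = best

    labels = np.where(assign, "positive", "negative")
    n = x.size
    within_sd = float(np.sqrt(ss / max(n - 2, 1)))
    return ClusterResult(labels=labels, center_neg=c_lo, center_pos=c_hi,
                         separation=c_hi - c_lo, within_sd=within_sd,
                         n_iter=n_iter)


def quality_gate(result: ClusterResult,
                 min_separation: float | None = None) -> bool:
    """Cluster-separation quality filter.

    Pass iff ``separation >= min_separation``; by default the bar is
    4 × the pooled within-cluster standard deviation, so a
    single-population image (separation of the order of the noise)
    fails while genuinely bimodal images pass. Sets and returns
    ``result.quality_ok``.
    """
    if min_separation is None:
        min_separation = 4.0 * result.within_sd
    result.quality_ok = bool(result.separation >= min_separation)
    return result.quality_ok
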