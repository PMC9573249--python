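"""Droplet detection in bright-field images.

The detector re-implements the classic multi-threshold blob-detection
scheme: the gray image is binarized at a ladder of thresholds
[T1, T1+t, T1+2t, ... T2]; connected components are extracted at every
level with their centroid, area, Crofton perimeter and convex-hull
area; detections whose centers coincide across levels are
merged into one droplet; and the merged droplets are screened by area,
circularity (4πA/P²) and convexity (A / convex area). The area window
[500, 2000] px² together with the two shape screens suppresses bright
spots (area out of range) and scratches (low circularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree

__all__ = [
    "DetectorParams",
    "Droplet",
    "BlobCandidate",
    "threshold_ladder",
    "components_with_shape",
    "circularity",
    "convexity",
    "merge_across_levels",
    "detect_droplets",
    "droplets_to_frame",
]

_EIGHT = np.ones((3, 3), dtype=np.int8)


@dataclass
class DetectorParams:
    """Threshold-ladder and screening settings.

    Ladder defaults suit an 8-bit bright field; the ladder bounds, the
    repeatability requirement and the grouping radius are calibration
    constants exposed here rather than fixed truths of the method.
    """

    t1: float = 40.0
    t2: float = 220.0
    step: float = 10.0
    min_area: float = 500.0
    max_area: float = 2000.0
    min_circularity: float = 0.7
    min_convexity: float = 0.85
    min_repeatability: int = 2
    grouping_radius: float = 4.0
    detect_dark: bool = False

    def validate(self) -> None:
        if self.t1 > self.t2:
            raise ValueError("ladder start t1 must not exceed end t2")
        if self.step <= 0:
            raise ValueError("ladder step must be positive")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not (0 <= self.min_circularity <= 1 and 0 <= self.min_convexity <= 1):
            raise ValueError("shape thresholds must lie in [0, 1]")
        if self.min_repeatability < 1:
            raise ValueError("min_repeatability must be >= 1")
        if self.grouping_radius <= 0:
            raise ValueError("grouping_radius must be positive")

    def ladder(self) -> np.ndarray:
        self.validate()
        n = int(math.floor((self.t2 - self.t1) / self.step + 1e-9)) + 1
        return self.t1 + self.step * np.arange(n)


@dataclass
class BlobCandidate:
    """One connected component at one threshold level."""
    center_x: float
    center_y: float
    area: float
    perimeter: float
    convex_area: float


@dataclass
class Droplet:
    """A detected droplet in pixel coordinates (0-based; x = column,
    y = row; centers at pixel centers)."""
    id: int
    center_x: float
    center_y: float
    radius: float
    area: float
    perimeter: float
    circularity: float
    convexity: float
    n_levels: int = 1
    edge_flag: bool = False
    signal: float | None = None
    label: str = "unset"  # positive | negative | rejected | unset
    rejected_reason: str = ""


def circularity(area: float, perimeter: float) -> float:
    """4π·Area/Perimeter², clipped to [0, 1]. 1 for a perfect circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return min(4.0 * math.pi * area / (perimeter * perimeter), 1.0)


def convexity(area: float, convex_area: float) -> float:
    """Area / convex-hull area; 1 for convex shapes."""
    if convex_area <= 0:
        raise ValueError("convex_area must be positive")
    return area / convex_area


def threshold_ladder(image: np.ndarray, params: DetectorParams):
    """Binarize the image at every ladder level.

    Yields ``(threshold, binary)`` pairs where foreground means
    pixel ≥ threshold (or ≤ threshold when ``detect_dark``).
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    img = np.asarray(image)
    for t in params.ladder():
        if params.detect_dark:
            yield t, img <= t
        else:
            yield t, img >= t


_CORNERS = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])

# 4-direction Crofton LUT over 2x2 pixel configurations (bit weights
# 1, 4, 2, 8 laid out as in skimage.measure.perimeter_crofton).
_SQ2 = math.sqrt(2.0)
_CROFTON_COEFS = np.array([
    0, math.pi / 4 * (1 + 1 / _SQ2), math.pi / (4 * _SQ2),
    math.pi / (2 * _SQ2), 0, math.pi / 4 * (1 + 1 / _SQ2), 0,
    math.pi / (4 * _SQ2), math.pi / 4, math.pi / 2, math.pi / (4 * _SQ2),
    math.pi / (4 * _SQ2), math.pi / 4, math.pi / 2, 0, 0])


def _crofton_per_label(labels: np.ndarray, n: int) -> np.ndarray:
    """Per-component 4-direction Crofton perimeter, length n+1
    (index = label). Each 2x2 block is attributed to the single
    component it touches (8-connected components never share a block).
    The estimator is close to unbiased for smooth digitized shapes,
    where a naive boundary-pixel trace would overestimate a disk's
    perimeter by ~5% and depress circularity to ~0.9.
    """
    lab = np.pad(labels, 1)
    fg = (lab > 0).astype(np.uint8)
    config = (fg[1:, 1:] + 4 * fg[1:, :-1] + 2 * fg[:-1, 1:]
              + 8 * fg[:-1, :-1])
    block_label = np.maximum(np.maximum(lab[1:, 1:], lab[1:, :-1]),
                             np.maximum(lab[:-1, 1:], lab[:-1, :-1]))
    return np.bincount(block_label.ravel(),
                       weights=_CROFTON_COEFS[config.ravel()],
                       minlength=n + 1)


def components_with_shape(binary: np.ndarray,
                          area_range: tuple[float, float] | None = None
                          ) -> list[BlobCandidate]:
    """Connected-component analysis of one binary image.

    8-connected components; center = centroid of the filled pixels;
    perimeter from the per-component Crofton estimate; convex-hull
    area as the exact hull of the pixel region, built from the corner
    points of its boundary pixels. ``area_range`` optionally skips the
    hull computation for components far outside the plausible droplet
    size (used by :func:`detect_droplets`; the public default keeps
    all).
    """
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    if area_range is None:
        keep = np.arange(1, n + 1)
    else:
        keep = np.nonzero((areas >= area_range[0])
                          & (areas <= area_range[1]))[0]
        keep = keep[keep > 0]
    if keep.size == 0:
        return []
    ys, xs = np.nonzero(binary)
    lab_fg = labels[ys, xs]
    sum_y = np.bincount(lab_fg, weights=ys, minlength=n + 1)
    sum_x = np.bincount(lab_fg, weights=xs, minlength=n + 1)
    perims = _crofton_per_label(labels, n)

    boundary = binary & ~ndimage.binary_erosion(binary)
    bys, bxs = np.nonzero(boundary)
    blab = labels[bys, bxs]
    order = np.argsort(blab, kind="stable")
    bys, bxs, blab = bys[order], bxs[order], blab[order]
    starts = np.searchsorted(blab, keep)
    stops = np.searchsorted(blab, keep, side="right")

    out: list[BlobCandidate] = []
    for lbl, i0, i1 in zip(keep, starts, stops):
        area = float(areas[lbl])
        pts = (np.column_stack([bys[i0:i1], bxs[i0:i1]])[:, None, :]
               + _CORNERS[None, :, :]).reshape(-1, 2)
        hull_area = area
        try:
            hull_area = float(ConvexHull(pts).volume)
        except (QhullError, ValueError):
            pass
        out.append(BlobCandidate(
            center_x=float(sum_x[lbl] / areas[lbl]),
            center_y=float(sum_y[lbl] / areas[lbl]),
            area=area,
            perimeter=max(float(perims[lbl]), 1e-9),
            convex_area=max(hull_area, area, 1.0)))
    return out


def merge_across_levels(candidates_per_level: list[list[BlobCandidate]],
                        params: DetectorParams) -> list[Droplet]:
    """Group per-level candidates whose centers agree within
    ``grouping_radius`` into droplets, then screen.

    Candidates are screened per level first (area window, circularity,
    convexity) so that degenerate representations of a blob at extreme
    thresholds — e.g. the bare bright rim of a droplet whose interior
    has dropped out — cannot join the group and skew its averages; the
    same screens are re-applied to the group means. A group must appear
    in at least ``min_repeatability`` ladder levels; its reported
    center, area, perimeter and hull area are per-group means, and the
    final shape descriptors are computed from those means.
    """
    params.validate()

    def _passes(c: BlobCandidate) -> bool:
        return (params.min_area <= c.area <= params.max_area
                and circularity(c.area, c.perimeter) >= params.min_circularity
                and convexity(c.area, c.convex_area) >= params.min_convexity)

    groups: list[dict] = []  # each: sums + count + levels
    centers: list[tuple[float, float]] = []
    for level_idx, all_cands in enumerate(candidates_per_level):
        cands = [c for c in all_cands if _passes(c)]
        if not cands:
            continue
        tree = cKDTree(np.asarray(centers)) if centers else None
        for c in cands:
            gi = -1
            if tree is not None:
                dist, j = tree.query((c.center_x, c.center_y),
                                     distance_upper_bound=params.grouping_radius)
                if np.isfinite(dist):
                    gi = int(j)
            if gi < 0:
                groups.append(dict(sx=0.0, sy=0.0, sa=0.0, sp=0.0, sh=0.0,
                                   n=0, levels=set()))
                gi = len(groups) - 1
            g = groups[gi]
            g["sx"] += c.center_x
            g["sy"] += c.center_y
            g["sa"] += c.area
            g["sp"] += c.perimeter
            g["sh"] += c.convex_area
            g["n"] += 1
            g["levels"].add(level_idx)
        # rebuild center list including new groups (running means)
        centers = [(g["sx"] / g["n"], g["sy"] / g["n"]) for g in groups]

    droplets: list[Droplet] = []
    for g in groups:
        if len(g["levels"]) < params.min_repeatability:
            continue
        n = g["n"]
        area = g["sa"] / n
        perim = g["sp"] / n
        hull = g["sh"] / n
        if not (params.min_area <= area <= params.max_area):
            continue
        circ = circularity(area, perim)
        conv = convexity(area, hull)
        if circ < params.min_circularity or conv < params.min_convexity:
            continue
        droplets.append(Droplet(
            id=len(droplets),
            center_x=g["sx"] / n, center_y=g["sy"] / n,
            radius=math.sqrt(area / math.pi),
            area=area, perimeter=perim,
            circularity=circ, convexity=min(conv, 1.0),
            n_levels=len(g["levels"])))
    return droplets


def detect_droplets(image: np.ndarray, params: DetectorParams | None = None
                    ) -> list[Droplet]:
    """Full bright-field droplet detection.

    Runs the threshold ladder, per-level component analysis (with a
    loose area pre-filter of [min_area/2, 2·max_area] to skip obvious
    non-droplets), cross-level merging and shape screening. Droplets
    whose bounding circle touches the image border are flagged
    ``edge_flag`` so downstream counting can exclude incomplete
    droplets at the frame edge.
    """
    if params is None:
        params = DetectorParams()
    params.validate()
    prefilter = (params.min_area / 2.0, params.max_area * 2.0)
    per_level = [components_with_shape(b, area_range=prefilter)
                 for _, b in threshold_ladder(image, params)]
    droplets = merge_across_levels(per_level, params)
    h, w = image.shape
    for d in droplets:
        if (d.center_x - d.radius < 0.5 or d.center_y - d.radius < 0.5
                or d.center_x + d.radius > w - 1.5
                or d.center_y + d.radius > h - 1.5):
            d.edge_flag = True
    return droplets


def droplets_to_frame(droplets: list[Droplet]) -> pd.DataFrame:
    cols = ["id", "center_x", "center_y", "radius", "area", "circularity",
            "convexity", "n_levels", "edge_flag", "signal", "label",
            "rejected_reason"]
    rows = [{c: getattr(d, c) for c in cols} for d in droplets]
    return pd.DataFrame(rows, columns=cols)
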