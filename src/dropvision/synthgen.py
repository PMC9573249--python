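"""Synthetic droplet-image generator with exact ground truth.

Renders matched bright-field / fluorescence image pairs that emulate a
monolayer of ~32.5 µm ddPCR droplets in a result-reading chip:

* bright-field droplets appear as bright rims with a moderately bright
  interior on a darker background (the detector keys on the filled
  interior/rim disk);
* fluorescence droplets are filled disks at their class intensity
  (positive or negative), multiplicatively attenuated by a quadratic
  vignetting surface and degraded by additive Gaussian noise;
* optional artifacts: large/small bright spots, thin bright scratches
  (bright-field only), dim background impurities at a fraction of the
  negative-droplet level (both images), and small satellite droplets
  attached to a parent droplet.

Every rendered object is recorded in a :class:`SceneTruth` so detection
and classification can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SceneParams",
    "TruthDroplet",
    "Artifact",
    "SceneTruth",
    "generate_scene",
    "generate_flat_field",
    "radial_vignette_coeffs",
    "vignette_surface",
    "expected_mix_fraction",
    "write_scene",
]

BF_MAX = 255.0  # bright field rendered at 8-bit depth
FL_MAX = 65535.0  # fluorescence rendered at 16-bit depth


@dataclass
class SceneParams:
    """Parameters of one synthetic field of view.

    Geometry defaults give droplets of radius ~16 px (area ~804 px²),
    squarely inside the [500, 2000] px² screening window used by the
    detector. Fluorescence class levels default to a 6:1
    positive/negative ratio with per-droplet intensity scatter equal to
    5% of the class separation.
    """

    image_width: int = 1024
    image_height: int = 1024
    n_droplets: int = 400
    droplet_radius_mean: float = 16.0
    droplet_radius_sd: float = 1.0
    positive_fraction: float = 0.3
    negative_mean: float = 2000.0
    positive_mean: float = 12000.0
    intensity_sd: float = 500.0
    vignette_coeffs: tuple[float, ...] | None = None
    n_bright_spots: int = 0
    n_scratches: int = 0
    n_impurities: int = 0
    impurity_level_frac: float = 0.5
    satellite_rate: float = 0.05
    noise_sd: float = 100.0
    seed: int = 0
    # Bright-field rendering levels (8-bit). The rim is the brightest
    # feature; the interior sits above the background so the filled
    # droplet disk is a stable bright blob across threshold levels.
    bf_background: float = 95.0
    bf_interior: float = 145.0
    bf_rim: float = 230.0
    bf_artifact_level: float = 245.0
    rim_thickness: float = 2.0
    bf_noise_sd: float = 2.0
    fl_background: float = 500.0

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.positive_mean <= self.negative_mean:
            raise ValueError("positive_mean must exceed negative_mean")
        if self.droplet_radius_mean <= 0:
            raise ValueError("droplet_radius_mean must be positive")
        if self.noise_sd < 0 or self.intensity_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0.0 <= self.satellite_rate <= 1.0:
            raise ValueError("satellite_rate must lie in [0, 1]")
        if self.vignette_coeffs is not None and len(self.vignette_coeffs) != 6:
            raise ValueError("vignette_coeffs must have six entries (a0..a5)")

    @classmethod
    def chip_field(cls, **overrides) -> "SceneParams":
        """A full-density field matching the droplet load of one
        result-reading-chip image (~1700 droplets of r≈16 px)."""
        base = dict(image_width=2048, image_height=2048, n_droplets=1700)
        base.update(overrides)
        return cls(**base)


@dataclass
class TruthDroplet:
    center_x: float
    center_y: float
    radius: float
    cls: str  # "positive" | "negative"
    true_intensity: float


@dataclass
class Artifact:
    kind: str  # bright_spot | scratch | impurity | satellite
    center_x: float
    center_y: float
    extent: float  # radius for disks, length for scratches


@dataclass
class SceneTruth:
    droplets: list[TruthDroplet] = field(default_factory=list)
    artifacts: list[Artifact] = field(default_factory=list)

    def droplet_frame(self) -> pd.DataFrame:
        rows = [
            dict(id=i, center_x=d.center_x, center_y=d.center_y,
                 radius=d.radius, cls=d.cls, true_intensity=d.true_intensity)
            for i, d in enumerate(self.droplets)
        ]
        return pd.DataFrame(rows, columns=["id", "center_x", "center_y",
                                           "radius", "cls", "true_intensity"])

    def artifact_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(a) for a in self.artifacts]
        return pd.DataFrame(rows, columns=["kind", "center_x", "center_y", "extent"])


def expected_mix_fraction(positive_parts: float, negative_parts: float) -> float:
    """Positive-droplet fraction expected when positive and negative
    droplet suspensions are mixed in the given volume ratio."""
    if positive_parts < 0 or negative_parts < 0:
        raise ValueError("mixing parts must be non-negative")
    total = positive_parts + negative_parts
    if total == 0:
        raise ValueError("at least one mixing part must be non-zero")
    return positive_parts / total


def vignette_surface(shape: tuple[int, int], coeffs) -> np.ndarray:
    """Evaluate the quadratic surface a0 + a1 x + a2 y + a3 x² + a4 xy + a5 y²
    over a pixel grid (x = column, y = row, 0-based)."""
    a0, a1, a2, a3, a4, a5 = coeffs
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    return a0 + a1 * x + a2 * y + a3 * x * x + a4 * x * y + a5 * y * y


def radial_vignette_coeffs(width: int, height: int,
                           corner_level: float = 0.55) -> tuple[float, ...]:
    """Quadratic coefficients of a radially symmetric vignette that is 1 at
    the frame center and falls to ``corner_level`` at the corners."""
    if not 0 < corner_level < 1:
        raise ValueError("corner_level must lie in (0, 1)")
    cx = (width - 1) / 2.0
    cy = (height - 1) / 2.0
    r2 = cx * cx + cy * cy
    k = (1.0 - corner_level) / r2
    # c(x,y) = 1 - k((x-cx)^2 + (y-cy)^2) expanded into a0..a5:
    return (1.0 - k * (cx * cx + cy * cy),
            2.0 * k * cx, 2.0 * k * cy, -k, 0.0, -k)


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float,
                value: float) -> None:
    """Alpha-blend an anti-aliased disk into ``img`` (in place).

    Boundary pixels get fractional coverage ≈ clip(r + 0.5 − d, 0, 1),
    which keeps the digitized area close to πr² and circularity near 1.
    """
    h, w = img.shape
    x0 = max(int(math.floor(cx - r - 2)), 0)
    x1 = min(int(math.ceil(cx + r + 2)) + 1, w)
    y0 = max(int(math.floor(cy - r - 2)), 0)
    y1 = min(int(math.ceil(cy + r + 2)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch *= (1.0 - alpha)
    patch += value * alpha


def _paint_segment(img: np.ndarray, p0, p1, width: float, value: float) -> None:
    """Alpha-blend an anti-aliased line segment of the given width."""
    h, w = img.shape
    (x0p, y0p), (x1p, y1p) = p0, p1
    pad = width / 2 + 2
    x0 = max(int(math.floor(min(x0p, x1p) - pad)), 0)
    x1 = min(int(math.ceil(max(x0p, x1p) + pad)) + 1, w)
    y0 = max(int(math.floor(min(y0p, y1p) - pad)), 0)
    y1 = min(int(math.ceil(max(y0p, y1p) + pad)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    vx, vy = x1p - x0p, y1p - y0p
    seg_len2 = vx * vx + vy * vy
    if seg_len2 == 0:
        t = np.zeros_like(xx, dtype=float)
    else:
        t = np.clip(((xx - x0p) * vx + (yy - y0p) * vy) / seg_len2, 0.0, 1.0)
    d = np.hypot(xx - (x0p + t * vx), yy - (y0p + t * vy))
    alpha = np.clip(width / 2 + 0.5 - d, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch *= (1.0 - alpha)
    patch += value * alpha


class _CellGrid:
    """Uniform-grid neighbor index for O(1) overlap queries during
    random sequential placement."""

    def __init__(self, width: float, height: float, cell: float):
        self.cell = cell
        self.nx = max(int(width / cell) + 1, 1)
        self.ny = max(int(height / cell) + 1, 1)
        self.cells: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x / self.cell), int(y / self.cell))

    def add(self, x: float, y: float, r: float) -> None:
        self.cells.setdefault(self._key(x, y), []).append((x, y, r))

    def clear_of(self, x: float, y: float, r: float, margin: float) -> bool:
        kx, ky = self._key(x, y)
        reach = int(math.ceil((r + margin + self.cell) / self.cell))
        for ix in range(kx - reach, kx + reach + 1):
            for iy in range(ky - reach, ky + reach + 1):
                for (ox, oy, orad) in self.cells.get((ix, iy), ()):
                    if math.hypot(x - ox, y - oy) <= r + orad + margin:
                        return False
        return True


def _seg_distance(px, py, x0, y0, x1, y1) -> float:
    vx, vy = x1 - x0, y1 - y0
    l2 = vx * vx + vy * vy
    if l2 == 0:
        return math.hypot(px - x0, py - y0)
    t = max(0.0, min(1.0, ((px - x0) * vx + (py - y0) * vy) / l2))
    return math.hypot(px - (x0 + t * vx), py - (y0 + t * vy))


def generate_scene(params: SceneParams):
    """Render one synthetic field of view.

    Returns ``(bright_field, fluorescence, truth)`` where the bright field
    is ``uint8``, the fluorescence ``uint16`` and ``truth`` a
    :class:`SceneTruth`. Identical params (including seed) reproduce the
    images bit for bit.

    Placement is seeded random sequential adsorption: artifacts are laid
    down first, then droplets are drawn uniformly and rejected if they
    overlap an existing object; impurities are placed like droplets.
    Raises ``RuntimeError`` if the requested density cannot be placed
    within a bounded number of attempts.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, h = params.image_width, params.image_height
    truth = SceneTruth()

    max_r = max(params.droplet_radius_mean + 4 * params.droplet_radius_sd, 8.0)
    grid = _CellGrid(w, h, cell=2 * max_r + 4)
    scratch_segs: list[tuple[float, float, float, float, float]] = []

    # --- artifacts first so droplets can avoid them -------------------
    spots = []
    for i in range(params.n_bright_spots):
        if i % 2 == 0:  # oversized spot, rejected by the area screen
            r = rng.uniform(28.0, 36.0)
        else:  # undersized speck, below the area window
            r = rng.uniform(7.0, 10.0)
        cx = rng.uniform(r + 2, w - 1 - r - 2)
        cy = rng.uniform(r + 2, h - 1 - r - 2)
        spots.append((cx, cy, r))
        grid.add(cx, cy, r)
        truth.artifacts.append(Artifact("bright_spot", cx, cy, r))
    for _ in range(params.n_scratches):
        length = rng.uniform(150.0, 300.0)
        width_px = rng.uniform(2.5, 3.5)
        ang = rng.uniform(0, 2 * math.pi)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        cy = rng.uniform(0.15 * h, 0.85 * h)
        dx, dy = math.cos(ang) * length / 2, math.sin(ang) * length / 2
        x0 = float(np.clip(cx - dx, 2, w - 3))
        y0 = float(np.clip(cy - dy, 2, h - 3))
        x1 = float(np.clip(cx + dx, 2, w - 3))
        y1 = float(np.clip(cy + dy, 2, h - 3))
        scratch_segs.append((x0, y0, x1, y1, width_px))
        truth.artifacts.append(
            Artifact("scratch", (x0 + x1) / 2, (y0 + y1) / 2,
                     math.hypot(x1 - x0, y1 - y0)))

    def _clear(cx, cy, r) -> bool:
        # 3 px edge-to-edge clearance: anti-aliased rims spread ~0.5 px
        # beyond the nominal radius, and touching rims would fuse two
        # droplets into one connected component (the detector does no
        # watershed splitting).
        if not grid.clear_of(cx, cy, r, margin=3.0):
            return False
        for (sx0, sy0, sx1, sy1, sw) in scratch_segs:
            if _seg_distance(cx, cy, sx0, sy0, sx1, sy1) <= r + sw / 2 + 3.0:
                return False
        return True

    # --- droplets and impurities by rejection sampling ----------------
    def _place_round(n: int, what: str, with_satellites: bool = False):
        """Place n non-overlapping disks; optionally pre-draw a satellite
        for each so the clearance check covers the satellite footprint
        (a satellite must never bridge to a neighboring droplet)."""
        placed = []
        attempts = 0
        max_attempts = max(2000, 400 * n)
        while len(placed) < n:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place {n} {what} after {max_attempts} attempts; "
                    "requested density is infeasible")
            attempts += 1
            r = float(np.clip(
                rng.normal(params.droplet_radius_mean, params.droplet_radius_sd),
                params.droplet_radius_mean - 3 * params.droplet_radius_sd,
                params.droplet_radius_mean + 3 * params.droplet_radius_sd))
            r = max(r, 4.0)
            sat = None
            r_eff = r
            if with_satellites and rng.random() < params.satellite_rate:
                sr = rng.uniform(3.0, 5.0)
                ang = rng.uniform(0, 2 * math.pi)
                dist = rng.uniform(0.9, 1.1) * r
                sat = (dist * math.cos(ang), dist * math.sin(ang), sr)
                r_eff = max(r, dist + sr)
            margin = r_eff + params.rim_thickness + 2
            if w - 1 - margin <= margin or h - 1 - margin <= margin:
                raise RuntimeError("image too small for requested droplet size")
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            if not _clear(cx, cy, r_eff):
                continue
            grid.add(cx, cy, r_eff)
            placed.append((cx, cy, r, sat))
        return placed

    droplet_geom = _place_round(params.n_droplets, "droplets",
                                with_satellites=True)
    impurity_geom = [(cx, cy, r) for (cx, cy, r, _)
                     in _place_round(params.n_impurities, "impurities")]

    satellites: list[tuple[float, float, float, float]] = []  # x, y, r, intensity
    for (cx, cy, r, sat) in droplet_geom:
        positive = rng.random() < params.positive_fraction
        mean = params.positive_mean if positive else params.negative_mean
        inten = float(np.clip(rng.normal(mean, params.intensity_sd), 1.0, FL_MAX))
        truth.droplets.append(TruthDroplet(cx, cy, r,
                                           "positive" if positive else "negative",
                                           inten))
        if sat is not None:
            dx, dy, sr = sat
            satellites.append((cx + dx, cy + dy, sr, inten))
            truth.artifacts.append(Artifact("satellite", cx + dx, cy + dy, sr))
    for (cx, cy, r) in impurity_geom:
        truth.artifacts.append(Artifact("impurity", cx, cy, r))

    # --- bright-field render ------------------------------------------
    bf = np.full((h, w), params.bf_background, dtype=np.float64)
    impurity_intensity = params.impurity_level_frac * params.negative_mean

    def _paint_rimmed(cx, cy, r):
        _paint_disk(bf, cx, cy, r, params.bf_rim)
        inner = r - params.rim_thickness
        if inner > 0.5:
            _paint_disk(bf, cx, cy, inner, params.bf_interior)

    for d in truth.droplets:
        _paint_rimmed(d.center_x, d.center_y, d.radius)
    for (cx, cy, r) in impurity_geom:
        _paint_rimmed(cx, cy, r)
    for (sx, sy, sr, _) in satellites:
        _paint_rimmed(sx, sy, sr)
    for (cx, cy, r) in spots:
        _paint_disk(bf, cx, cy, r, params.bf_artifact_level)
    for (x0, y0, x1, y1, sw) in scratch_segs:
        _paint_segment(bf, (x0, y0), (x1, y1), sw, params.bf_artifact_level)
    if params.bf_noise_sd > 0:
        bf += rng.normal(0.0, params.bf_noise_sd, bf.shape)
    bright_field = np.clip(bf, 0, BF_MAX).astype(np.uint8)

    # --- fluorescence render ------------------------------------------
    fl = np.full((h, w), params.fl_background, dtype=np.float64)
    for d in truth.droplets:
        _paint_disk(fl, d.center_x, d.center_y, d.radius, d.true_intensity)
    for (sx, sy, sr, inten) in satellites:
        _paint_disk(fl, sx, sy, sr, inten)
    for (cx, cy, r) in impurity_geom:
        _paint_disk(fl, cx, cy, r, impurity_intensity)
    if params.vignette_coeffs is not None:
        surf = vignette_surface((h, w), params.vignette_coeffs)
        if surf.max() <= 0:
            raise ValueError("vignette surface is non-positive over the image")
        fl *= np.clip(surf / surf.max(), 0.0, None)
    if params.noise_sd > 0:
        fl += rng.normal(0.0, params.noise_sd, fl.shape)
    fluorescence = np.clip(fl, 0, FL_MAX).astype(np.uint16)

    return bright_field, fluorescence, truth


def generate_flat_field(params: SceneParams, level: float = 10000.0,
                        seed: int | None = None) -> np.ndarray:
    """Render a droplet-free uniform-fluorophore calibration frame:
    constant emission ``level`` under the scene's vignette, plus noise.
    Used as the input for vignetting-model estimation."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h, w = params.image_height, params.image_width
    img = np.full((h, w), float(level), dtype=np.float64)
    if params.vignette_coeffs is not None:
        surf = vignette_surface((h, w), params.vignette_coeffs)
        if surf.max() <= 0:
            raise ValueError("vignette surface is non-positive over the image")
        img *= np.clip(surf / surf.max(), 0.0, None)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0, FL_MAX).astype(np.uint16)


def write_scene(out_dir, stem: str, bright_field: np.ndarray,
                fluorescence: np.ndarray, truth: SceneTruth,
                params: SceneParams | None = None) -> dict:
    """Write a scene to ``out_dir``: 16-/8-bit TIFFs, truth CSVs and a
    JSON parameter sidecar. Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bright_field": out / f"{stem}_bf.tif",
        "fluorescence": out / f"{stem}_fl.tif",
        "droplets": out / f"{stem}_truth_droplets.csv",
        "artifacts": out / f"{stem}_truth_artifacts.csv",
    }
    tifffile.imwrite(paths["bright_field"], bright_field)
    tifffile.imwrite(paths["fluorescence"], fluorescence)
    truth.droplet_frame().to_csv(paths["droplets"], index=False)
    truth.artifact_frame().to_csv(paths["artifacts"], index=False)
    if params is not None:
        sidecar = out / f"{stem}_params.json"
        sidecar.write_text(json.dumps(dataclasses.asdict(params), indent=2))
        paths["params"] = sidecar
    return {k: str(v) for k, v in paths.items()}
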