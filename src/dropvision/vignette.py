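"""Fluorescence vignetting estimation and correction.

The optics of a fixed-camera droplet reader attenuate the image toward
the frame edges. A calibration frame of uniform fluorophore is blurred
with repeated 3×3 Gaussian passes to erase texture, the blurred template
is fitted with a quadratic surface

    c(x, y) = a0 + a1·x + a2·y + a3·x² + a4·x·y + a5·y²

by linear least squares, and the surface's maximum divided by the
surface gives a multiplicative gain map (gain 1 at the brightest point,
> 1 toward the edges) that flattens subsequent images. Image uniformity
is scored as the average difference between the center tile and the
eight edge tiles of a 3×3 partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VignetteModel",
    "gaussian_blur_3x3",
    "fit_surface",
    "correct_image",
    "uniformity_metric",
    "evaluate_surface",
]

_K1D = np.array([1.0, 2.0, 1.0]) / 4.0  # separable factor of the 3x3 kernel /16


def gaussian_blur_3x3(image: np.ndarray, passes: int = 1) -> np.ndarray:
    """Repeatedly convolve with the 3×3 binomial kernel
    (1,2,1; 2,4,2; 1,2,1)/16 (applied separably), edge-replicated
    borders, floating-point output."""
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    out = np.asarray(image, dtype=np.float64)
    for _ in range(passes):
        out = ndimage.convolve1d(out, _K1D, axis=0, mode="nearest")
        out = ndimage.convolve1d(out, _K1D, axis=1, mode="nearest")
    return out


def evaluate_surface(coeffs, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate the quadratic surface over an image grid (x = column)."""
    a0, a1, a2, a3, a4, a5 = coeffs
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    return a0 + a1 * x + a2 * y + a3 * x * x + a4 * x * y + a5 * y * y


def _surface_max(coeffs, shape: tuple[int, int], surface: np.ndarray) -> float:
    """Maximum of the quadratic over the image domain: the analytic
    stationary point when it is an interior maximum, otherwise the grid
    maximum."""
    _, a1, a2, a3, a4, a5 = coeffs
    hess = np.array([[2 * a3, a4], [a4, 2 * a5]])
    det = np.linalg.det(hess)
    if det > 0 and 2 * a3 < 0:  # negative definite -> interior maximum exists
        x0, y0 = np.linalg.solve(hess, [-a1, -a2])
        h, w = shape
        if 0 <= x0 <= w - 1 and 0 <= y0 <= h - 1:
            a0 = coeffs[0]
            return float(a0 + a1 * x0 + a2 * y0 + a3 * x0 * x0
                         + a4 * x0 * y0 + a5 * y0 * y0)
    return float(surface.max())


@dataclass
class VignetteModel:
    """Fitted quadratic illumination surface and its gain map."""

    coeffs: np.ndarray  # (6,) a0..a5
    gain_map: np.ndarray  # multiplicative correction, min exactly 1
    fit_residual_rms: float
    image_shape: tuple[int, int]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "coeffs": [float(c) for c in self.coeffs],
            "shape": list(self.image_shape),
            "residual_rms": float(self.fit_residual_rms),
        }))

    @classmethod
    def from_json(cls, path, gain_clip: float = 10.0) -> "VignetteModel":
        d = json.loads(Path(path).read_text())
        return build_model(np.asarray(d["coeffs"], dtype=float),
                           tuple(d["shape"]), float(d["residual_rms"]),
                           gain_clip=gain_clip)


def build_model(coeffs: np.ndarray, shape: tuple[int, int],
                residual_rms: float, gain_clip: float = 10.0) -> VignetteModel:
    surface = evaluate_surface(coeffs, shape)
    if surface.min() <= 0:
        raise ValueError("fitted surface is non-positive inside the image "
                         "(degenerate vignette)")
    cmax = _surface_max(coeffs, shape, surface)
    gain = cmax / surface
    gain /= gain.min()  # pin gain to exactly 1 at the surface maximum
    np.clip(gain, 1.0, gain_clip, out=gain)
    return VignetteModel(np.asarray(coeffs, dtype=float), gain,
                         float(residual_rms), tuple(shape))


def fit_surface(template: np.ndarray, sample_stride: int = 8,
                gain_clip: float = 10.0) -> VignetteModel:
    """Least-squares quadratic fit of the (blurred) template.

    Samples the template on a regular grid with the given stride and
    solves for a0..a5 with a QR-based least-squares solve. Raises on a
    rank-deficient design (e.g. collinear samples) and when the fitted
    surface dips to zero or below inside the frame.
    """
    template = np.asarray(template, dtype=np.float64)
    if template.ndim != 2 or min(template.shape) < 3:
        raise ValueError("template must be a 2-D image of at least 3x3")
    if sample_stride < 1:
        raise ValueError("sample_stride must be >= 1")
    h, w = template.shape
    ys = np.arange(0, h, sample_stride, dtype=np.float64)
    xs = np.arange(0, w, sample_stride, dtype=np.float64)
    if ys.size * xs.size < 6:
        raise ValueError("need at least 6 sample points for a quadratic fit")
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    x = gx.ravel()
    y = gy.ravel()
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    z = template[gy.astype(int), gx.astype(int)].ravel()
    coeffs, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < 6:
        raise ValueError("rank-deficient design: sample grid does not "
                         "determine a quadratic surface")
    resid = z - design @ coeffs
    rms = float(np.sqrt(np.mean(resid * resid)))
    return build_model(coeffs, (h, w), rms, gain_clip=gain_clip)


def correct_image(image: np.ndarray, model: VignetteModel,
                  max_value: float = 65535.0) -> np.ndarray:
    """Multiply by the gain map; output is float64 clipped to
    [0, max_value] (16-bit range by default)."""
    if tuple(image.shape) != tuple(model.image_shape):
        raise ValueError(f"image shape {image.shape} does not match model "
                         f"shape {model.image_shape}")
    out = np.asarray(image, dtype=np.float64) * model.gain_map
    return np.clip(out, 0.0, max_value)


def uniformity_metric(image: np.ndarray) -> float:
    """Average of (center-tile mean − edge-tile mean) over the eight
    edge tiles of a 3×3 partition (remainder rows/columns truncated).
    0 for a flat image; large and positive for center-bright
    vignetting."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    th, tw = image.shape[0] // 3, image.shape[1] // 3
    means = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            means[i, j] = image[i * th:(i + 1) * th, j * tw:(j + 1) * tw].mean()
    center = means[1, 1]
    edges = np.delete(means.ravel(), 4)
    return float(np.mean(center - edges))
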