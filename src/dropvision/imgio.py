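"""Grayscale image reading and writing (TIFF via tifffile, other
formats via imageio). Images are 2-D numpy arrays throughout; pixel
coordinates are 0-based with x = column increasing right and y = row
increasing down, centers at pixel centers."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def read_gray(path) -> np.ndarray:
    """Read a single-channel image; multi-channel input is rejected."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(p)
    else:
        img = iio.imread(p)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    if img.ndim != 2:
        raise ValueError(f"{p} is not a single-channel grayscale image "
                         f"(shape {img.shape})")
    return img


def write_gray(path, image: np.ndarray) -> None:
    """Write a 2-D array; float input is rounded and saved as 16-bit."""
    p = Path(path)
    img = np.asarray(image)
    if img.dtype.kind == "f":
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, img)
    else:
        iio.imwrite(p, img)
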