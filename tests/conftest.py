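import numpy as np
import pytest

from dropvision import (DetectorParams, SceneParams, generate_flat_field,
                        generate_scene, fit_surface, gaussian_blur_3x3,
                        radial_vignette_coeffs)


@pytest.fixture(scope="session")
def small_scene_params():
    """A light field of view used across unit tests: 768 px, 220
    droplets, a few artifacts, quadratic vignette."""
    return SceneParams(
        image_width=768, image_height=768, n_droplets=220,
        n_bright_spots=4, n_scratches=2,
        vignette_coeffs=radial_vignette_coeffs(768, 768),
        seed=7)


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return generate_scene(small_scene_params)


@pytest.fixture(scope="session")
def small_vignette_model(small_scene_params):
    flat = generate_flat_field(small_scene_params, level=10000.0, seed=99)
    return fit_surface(gaussian_blur_3x3(flat, passes=50), sample_stride=8)


@pytest.fixture(scope="session")
def detector_params():
    return DetectorParams()


def render_disk(shape, cx, cy, r, value=1.0, background=0.0):
    """Hard-edged disk image used as a minimal detector input."""
    img = np.full(shape, background, dtype=np.float64)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[np.hypot(xx - cx, yy - cy) <= r] = value
    return img
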