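"""Vignetting model: blur kernel, surface fit round trips, correction
and the edge-vs-center uniformity statistic."""

import numpy as np
import pytest

from dropvision import (correct_image, fit_surface, gaussian_blur_3x3,
                        generate_flat_field, radial_vignette_coeffs,
                        uniformity_metric)
from dropvision.synthgen import SceneParams
from dropvision.vignette import build_model, evaluate_surface

KERNEL = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]]) / 16.0


def test_blur_preserves_constant_images():
    img = np.full((64, 48), 500.0)
    for passes in (1, 5):
        assert np.allclose(gaussian_blur_3x3(img, passes), 500.0)


def test_impulse_response_is_the_3x3_binomial_kernel():
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    out = gaussian_blur_3x3(img, passes=1)
    assert np.allclose(out[9:12, 9:12], KERNEL, atol=1e-12)
    assert out.sum() == pytest.approx(1.0)


def test_blur_conserves_interior_mass_against_direct_convolution():
    rng = np.random.default_rng(4)
    img = rng.uniform(0, 1000, (32, 32))
    out = gaussian_blur_3x3(img, passes=1)
    # direct 3x3 weighted-average oracle at interior pixels
    for (y, x) in [(5, 7), (16, 16), (25, 9)]:
        expected = np.sum(img[y - 1:y + 2, x - 1:x + 2] * KERNEL)
        assert out[y, x] == pytest.approx(expected, rel=1e-12)


def test_blur_rejects_bad_pass_count():
    with pytest.raises(ValueError):
        gaussian_blur_3x3(np.zeros((8, 8)), passes=0)


def test_surface_fit_recovers_known_coefficients_exactly():
    coeffs = (1000.0, 0.2, -0.1, -4e-4, 0.0, -5e-4)
    template = evaluate_surface(coeffs, (300, 400))
    model = fit_surface(template, sample_stride=8)
    assert np.allclose(model.coeffs, coeffs, rtol=1e-6, atol=1e-10)
    assert model.fit_residual_rms < 1e-6


def test_flat_template_yields_identity_model():
    model = fit_surface(np.full((100, 100), 1234.0))
    assert model.coeffs[0] == pytest.approx(1234.0)
    assert np.allclose(model.coeffs[1:], 0.0, atol=1e-9)
    assert np.allclose(model.gain_map, 1.0)


def test_underdetermined_and_degenerate_fits_raise():
    with pytest.raises(ValueError):
        fit_surface(np.ones((10, 10)), sample_stride=10)  # < 6 samples
    ramp = evaluate_surface((10.0, -2.0, 0.0, 0.0, 0.0, 0.0), (50, 50))
    with pytest.raises(ValueError, match="non-positive"):
        fit_surface(ramp)  # surface crosses zero inside the frame


def test_noisy_recovery_within_stated_tolerances():
    coeffs = (20000.0, 1.0, -0.8, -6e-3, 0.0, -5e-3)
    rng = np.random.default_rng(8)
    template = evaluate_surface(coeffs, (512, 512))
    noisy = template + rng.normal(0, 50, template.shape)
    model = fit_surface(gaussian_blur_3x3(noisy, passes=10), sample_stride=4)
    assert model.coeffs[0] == pytest.approx(coeffs[0], rel=0.01)
    assert model.coeffs[3] == pytest.approx(coeffs[3], rel=0.10)
    assert model.coeffs[5] == pytest.approx(coeffs[5], rel=0.10)


def test_analytic_argmax_agrees_with_grid_argmax():
    coeffs = (1000.0, 0.6, 0.4, -2e-3, 1e-4, -3e-3)
    surf = evaluate_surface(coeffs, (256, 256))
    model = build_model(np.asarray(coeffs), (256, 256), 0.0)
    grid_max = surf.max()
    # the gain map is 1 exactly where the surface is largest
    iy, ix = np.unravel_index(np.argmax(surf), surf.shape)
    assert model.gain_map[iy, ix] == pytest.approx(1.0, abs=1e-6)
    assert np.all(model.gain_map >= 1.0)


def test_identity_gain_returns_input():
    model = build_model(np.array([500.0, 0, 0, 0, 0, 0]), (64, 64), 0.0)
    assert np.all(model.gain_map == 1.0)
    img = np.arange(64 * 64, dtype=float).reshape(64, 64)
    assert np.array_equal(correct_image(img, model), img)


def test_shape_mismatch_rejected():
    model = fit_surface(np.full((64, 64), 500.0))
    with pytest.raises(ValueError):
        correct_image(np.zeros((32, 32)), model)


def test_vignetted_flat_field_round_trip_within_one_percent():
    params = SceneParams(image_width=512, image_height=512, n_droplets=0,
                         vignette_coeffs=radial_vignette_coeffs(512, 512),
                         noise_sd=0.0, seed=0)
    flat = generate_flat_field(params, level=20000.0).astype(float)
    model = fit_surface(gaussian_blur_3x3(flat, passes=5))
    corrected = correct_image(flat, model)
    interior = corrected[5:-5, 5:-5]
    assert np.all(np.abs(interior - interior.max()) / interior.max() < 0.01)


def test_correction_idempotent_in_the_limit():
    params = SceneParams(image_width=256, image_height=256, n_droplets=0,
                         vignette_coeffs=radial_vignette_coeffs(256, 256),
                         noise_sd=0.0, seed=0)
    flat = generate_flat_field(params, level=20000.0).astype(float)
    once = correct_image(flat, fit_surface(gaussian_blur_3x3(flat, 5)))
    refit = fit_surface(gaussian_blur_3x3(once, 5))
    twice = correct_image(once, refit)
    assert np.all(np.abs(twice - once) / np.maximum(once, 1) < 0.005)


def test_uniformity_metric_values_and_errors():
    assert uniformity_metric(np.full((90, 90), 777.0)) == 0.0
    img = np.full((90, 90), 900.0)
    img[30:60, 30:60] = 1000.0  # center tile only
    assert uniformity_metric(img) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        uniformity_metric(np.zeros((2, 5)))


@pytest.mark.parametrize("seed", [1, 2])
def test_correction_reduces_uniformity_metric(seed):
    params = SceneParams(image_width=384, image_height=384, n_droplets=0,
                         vignette_coeffs=radial_vignette_coeffs(384, 384),
                         noise_sd=30.0, seed=seed)
    flat = generate_flat_field(params, level=20000.0)
    model = fit_surface(gaussian_blur_3x3(flat, passes=20))
    raw = uniformity_metric(flat)
    cor = uniformity_metric(correct_image(flat, model))
    assert raw > 0
    assert cor < 0.15 * raw


def test_model_json_round_trip(tmp_path):
    coeffs = (1000.0, 0.2, -0.1, -4e-4, 0.0, -5e-4)
    model = fit_surface(evaluate_surface(coeffs, (128, 128)))
    path = tmp_path / "model.json"
    model.to_json(path)
    from dropvision.vignette import VignetteModel
    loaded = VignetteModel.from_json(path)
    assert np.allclose(loaded.coeffs, model.coeffs)
    assert loaded.image_shape == model.image_shape
    assert np.allclose(loaded.gain_map, model.gain_map, rtol=1e-9)
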