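"""Detector unit tests: ladder construction, component measurement
against brute-force oracles, shape descriptors and full detection
against generator ground truth."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage

from dropvision import DetectorParams, circularity, convexity, detect_droplets
from dropvision.blobdetect import (components_with_shape, merge_across_levels,
                                   threshold_ladder)
from dropvision.metrics import match_points
from conftest import render_disk


# --- threshold ladder -------------------------------------------------

def test_ladder_enumerates_t1_to_t2_inclusive():
    p = DetectorParams(t1=50, t2=250, step=50)
    assert list(p.ladder()) == [50, 100, 150, 200, 250]


def test_constant_image_thresholding():
    img = np.full((32, 32), 100.0)
    p = DetectorParams(t1=50, t2=150, step=100)
    (t_lo, b_lo), (t_hi, b_hi) = list(threshold_ladder(img, p))
    assert b_lo.all() and not b_hi.any()


def test_ladder_equals_pixelwise_comparison_oracle():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, size=(40, 40))
    p = DetectorParams(t1=40, t2=220, step=10)
    for t, binary in threshold_ladder(img, p):
        assert np.array_equal(binary, img >= t)
    p_dark = dataclasses.replace(p, detect_dark=True)
    for t, binary in threshold_ladder(img, p_dark):
        assert np.array_equal(binary, img <= t)


def test_empty_ladder_raises():
    with pytest.raises(ValueError):
        DetectorParams(t1=200, t2=100).ladder()


# --- component measurement -------------------------------------------

def test_disk_centroid_recovered_within_half_pixel():
    img = render_disk((256, 256), cx=100, cy=120, r=16) > 0.5
    cands = components_with_shape(img)
    assert len(cands) == 1
    assert cands[0].center_x == pytest.approx(100, abs=0.5)
    assert cands[0].center_y == pytest.approx(120, abs=0.5)


def test_two_disjoint_disks_counted_with_label_oracle():
    img = (render_disk((256, 256), 60, 60, 14)
           + render_disk((256, 256), 180, 170, 18)) > 0.5
    cands = components_with_shape(img)
    labels, n = ndimage.label(img, structure=np.ones((3, 3)))
    oracle_areas = sorted(np.bincount(labels.ravel())[1:])
    assert n == len(cands) == 2
    assert sorted(c.area for c in cands) == pytest.approx(oracle_areas)


def test_filled_square_area_equals_hull_area():
    img = np.zeros((60, 60), bool)
    img[15:45, 15:45] = True
    (c,) = components_with_shape(img)
    assert c.area == 900
    assert c.convex_area == pytest.approx(900, abs=1e-9)


def test_plus_sign_hull_from_pixel_corner_oracle():
    """Concave shape: hull area must equal the brute-force hull of all
    pixel corner points, and convexity must be well below 1."""
    from scipy.spatial import ConvexHull
    img = np.zeros((80, 80), bool)
    img[35:45, 20:60] = True  # horizontal 40x10 bar
    img[20:60, 35:45] = True  # vertical 40x10 bar
    (c,) = components_with_shape(img)
    assert c.area == 700
    ys, xs = np.nonzero(img)
    corners = np.concatenate([np.column_stack([ys + dy, xs + dx])
                              for dy in (-0.5, 0.5) for dx in (-0.5, 0.5)])
    oracle = ConvexHull(corners).volume
    assert c.convex_area == pytest.approx(oracle, rel=1e-9)
    assert convexity(c.area, c.convex_area) < 0.75


def test_empty_image_yields_no_candidates():
    assert components_with_shape(np.zeros((64, 64), bool)) == []


def test_per_component_perimeter_matches_library_crofton_oracle():
    """The vectorized per-component Crofton perimeter must equal the
    established library estimator run on each component in isolation."""
    from skimage.measure import perimeter_crofton
    rng = np.random.default_rng(1)
    img = np.zeros((220, 220), bool)
    for _ in range(10):
        cx, cy = rng.uniform(15, 205, 2)
        r = rng.uniform(3, 12)
        img |= render_disk((220, 220), cx, cy, r) > 0.5
    labels, n = ndimage.label(img, structure=np.ones((3, 3)))
    cands = sorted(components_with_shape(img), key=lambda c: (c.center_y,
                                                              c.center_x))
    assert len(cands) == n
    refs = sorted(
        ((ndimage.center_of_mass(labels == i)[0],
          ndimage.center_of_mass(labels == i)[1],
          perimeter_crofton(labels == i, directions=4))
         for i in range(1, n + 1)))
    for c, (ry, rx, rp) in zip(cands, refs):
        assert c.perimeter == pytest.approx(rp, rel=1e-12)


# --- shape descriptors -----------------------------------------------

def test_circularity_closed_forms():
    r, s = 16.0, 9.0
    assert circularity(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)
    assert circularity(s * s, 4 * s) == pytest.approx(math.pi / 4, abs=0.02)


def test_circularity_clipped_at_one():
    assert circularity(1000.0, 1.0) == 1.0


def test_shape_descriptor_preconditions():
    with pytest.raises(ValueError):
        circularity(100.0, 0.0)
    with pytest.raises(ValueError):
        convexity(100.0, 0.0)


def test_digitized_disk_circularity_near_one_scratch_low(detector_params):
    from dropvision import SceneParams, generate_scene
    p = SceneParams(image_width=512, image_height=512, n_droplets=60,
                    satellite_rate=0.0, seed=19)
    bf, _, _ = generate_scene(p)
    droplets = detect_droplets(bf, detector_params)
    assert droplets and min(d.circularity for d in droplets) >= 0.9
    # a bare synthetic scratch must score far below the screen
    img = np.zeros((120, 320), bool)
    img[58:61, 20:300] = True
    (c,) = components_with_shape(img)
    assert circularity(c.area, c.perimeter) <= 0.3


# --- merging and screening -------------------------------------------

def _disk_candidates(n_levels=5, jitter=0.0):
    img = render_disk((128, 128), 64, 64, 16) > 0.5
    base = components_with_shape(img)[0]
    out = []
    for i in range(n_levels):
        c = dataclasses.replace(base)
        c.center_x += jitter * i
        out.append([c])
    return out


def test_stable_center_across_levels_merges_to_one_droplet():
    droplets = merge_across_levels(_disk_candidates(5, jitter=0.2),
                                   DetectorParams())
    assert len(droplets) == 1
    assert droplets[0].n_levels == 5


def test_min_repeatability_filters_single_level_detections():
    cands = _disk_candidates(1)
    assert merge_across_levels(cands, DetectorParams(min_repeatability=2)) == []


def test_small_disk_rejected_by_area_window():
    """r=12 -> area ~452 px, below the [500, 2000] px screening window."""
    img = render_disk((128, 128), 64, 64, 12) > 0.5
    cands = [components_with_shape(img)] * 3
    assert merge_across_levels(cands, DetectorParams()) == []
    relaxed = DetectorParams(min_area=100)
    assert len(merge_across_levels(cands, relaxed)) == 1


def test_screening_is_monotone_in_thresholds(small_scene, detector_params):
    """Raising min_circularity or narrowing the area window can only
    shrink the detection list."""
    bf, _, _ = small_scene
    n_base = len(detect_droplets(bf, detector_params))
    tighter_circ = dataclasses.replace(detector_params, min_circularity=0.95)
    narrower_area = dataclasses.replace(detector_params,
                                        min_area=700, max_area=1100)
    assert len(detect_droplets(bf, tighter_circ)) <= n_base
    assert len(detect_droplets(bf, narrower_area)) <= n_base


# --- full detection ---------------------------------------------------

def test_detection_matches_ground_truth_despite_artifacts(small_scene,
                                                          detector_params):
    """All synthetic droplets recovered within 2 px; the injected bright
    spots and scratches yield no detections at artifact sites."""
    bf, _, truth = small_scene
    droplets = [d for d in detect_droplets(bf, detector_params)
                if not d.edge_flag]
    txy = np.array([[t.center_x, t.center_y] for t in truth.droplets])
    dxy = np.array([[d.center_x, d.center_y] for d in droplets])
    pairs, unmatched_truth, unmatched_det = match_points(txy, dxy, 2.0)
    assert len(unmatched_truth) == 0
    assert len(unmatched_det) == 0
    matched_r = [abs(droplets[di].radius - truth.droplets[ti].radius)
                 for ti, di in pairs]
    assert np.mean(matched_r) < 1.0


def test_empty_background_image_gives_no_droplets():
    img = np.full((256, 256), 95, dtype=np.uint8)
    assert detect_droplets(img, DetectorParams()) == []


def test_border_crossing_droplet_is_edge_flagged():
    img = np.full((200, 200), 60.0)
    img[render_disk((200, 200), 14, 100, 16) > 0.5] = 160.0
    img[render_disk((200, 200), 100, 100, 16) > 0.5] = 160.0
    p = DetectorParams(t1=80, t2=150, step=10)
    droplets = detect_droplets(img, p)
    flags = {round(d.center_x): d.edge_flag for d in droplets}
    assert flags.get(14) is True
    assert flags.get(100) is False
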