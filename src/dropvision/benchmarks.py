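"""Synthetic end-to-end benchmarks.

These routines generate full-density fields of view (2048×2048 px,
~1700 droplets of radius ~16 px — the droplet load of one
result-reading-chip image), run the complete pipeline on them and score
it against the generator's ground truth:

* detection recall on bright-field images with injected bright spots
  and scratches;
* mean per-image positive/negative classification accuracy on
  vignetted two-class fluorescence images;
* the four-level concentration-gradient experiment (positive fractions
  44.44%, 27.50%, 17.18%, 10.72% from a 4:5 mix and serial dilution),
  four replicates per level, scored by the Pearson correlation of
  measured versus true positive fractions.
"""

from __future__ import annotations

import numpy as np

from .metrics import gradient_report, match_points
from .pipeline import analyze_field
from .signal import SignalParams
from .synthgen import SceneParams, generate_flat_field, generate_scene, \
    radial_vignette_coeffs
from .vignette import fit_surface, gaussian_blur_3x3

__all__ = ["GRADIENT_LEVELS", "benchmark_scene_params",
           "fit_benchmark_vignette", "benchmark_detection_classification",
           "benchmark_gradient"]

#: True positive-droplet fractions of the serial-dilution gradient
#: (the first level is the 4:5 mix, 4/9 = 44.44%).
GRADIENT_LEVELS = (0.4444, 0.2750, 0.1718, 0.1072)

_FIELD = 2048
_DROPLETS_PER_FIELD = 1700


def benchmark_scene_params(seed: int, positive_fraction: float = 0.3,
                           with_artifacts: bool = True) -> SceneParams:
    """The benchmark field: chip-density droplets, radial vignetting
    falling to 55% at the corners, class means 2000/12000 (ratio 6),
    per-droplet intensity scatter of 5% of the class separation, and —
    when ``with_artifacts`` — 5 bright spots and 3 scratches."""
    return SceneParams.chip_field(
        n_droplets=_DROPLETS_PER_FIELD,
        positive_fraction=positive_fraction,
        vignette_coeffs=radial_vignette_coeffs(_FIELD, _FIELD),
        n_bright_spots=5 if with_artifacts else 0,
        n_scratches=3 if with_artifacts else 0,
        seed=seed)


def fit_benchmark_vignette(seed: int, blur_passes: int = 50):
    """Vignette model from one uniform-fluorophore calibration frame
    rendered under the benchmark's vignetting surface."""
    flat = generate_flat_field(benchmark_scene_params(seed), level=10000.0,
                               seed=seed)
    return fit_surface(gaussian_blur_3x3(flat, passes=blur_passes),
                       sample_stride=8)


def _field_scores(params: SceneParams, model, match_tol: float = 2.0):
    """One field through the full chain; returns (n_truth, n_recalled,
    n_classified, n_correct, measured_fraction_counts)."""
    bf, fl, truth = generate_scene(params)
    res = analyze_field(bf, fl, vignette_model=model,
                        signal_params=SignalParams())
    detected = [d for d in res.droplets if not d.edge_flag]
    txy = np.array([[t.center_x, t.center_y] for t in truth.droplets])
    dxy = np.array([[d.center_x, d.center_y] for d in detected])
    pairs, _, _ = match_points(txy, dxy, match_tol)
    n_correct = 0
    n_classified = 0
    for ti, di in pairs:
        lab = detected[di].label
        if lab in ("positive", "negative"):
            n_classified += 1
            n_correct += int(lab == truth.droplets[ti].cls)
    return (len(truth.droplets), len(pairs), n_classified, n_correct,
            res.n_pos, res.n_neg)


def benchmark_detection_classification(seed: int, n_fields: int = 20) -> dict:
    """Detection recall and mean per-image classification accuracy over
    ``n_fields`` benchmark fields (a single shared vignette model is
    fitted from a calibration frame, as in per-channel calibration)."""
    rng = np.random.default_rng(seed)
    field_seeds = rng.integers(0, 2**31 - 1, size=n_fields)
    model = fit_benchmark_vignette(int(rng.integers(0, 2**31 - 1)))
    n_truth_total = 0
    n_recalled_total = 0
    accuracies = []
    for fs in field_seeds:
        params = benchmark_scene_params(int(fs))
        n_truth, n_rec, n_cls, n_ok, _, _ = _field_scores(params, model)
        n_truth_total += n_truth
        n_recalled_total += n_rec
        if n_cls:
            accuracies.append(n_ok / n_cls)
    return {
        "n_fields": n_fields,
        "n_truth_droplets": n_truth_total,
        "detection_recall_pct": 100.0 * n_recalled_total / n_truth_total,
        "mean_classification_accuracy_pct": 100.0 * float(np.mean(accuracies)),
    }


def benchmark_gradient(seed: int, n_replicates: int = 4,
                       fields_per_replicate: int = 6) -> dict:
    """Simulated four-level concentration gradient.

    Each replicate is ``fields_per_replicate`` benchmark fields
    (~10,000 droplets per sample); droplets are pooled within a
    replicate to one measured positive fraction; per-level means feed
    the Pearson correlation against the true fractions."""
    rng = np.random.default_rng(seed)
    model = fit_benchmark_vignette(int(rng.integers(0, 2**31 - 1)))
    pairs = []
    n_droplets = 0
    for level in GRADIENT_LEVELS:
        for _ in range(n_replicates):
            n_pos = n_neg = 0
            for _ in range(fields_per_replicate):
                params = benchmark_scene_params(
                    int(rng.integers(0, 2**31 - 1)),
                    positive_fraction=level, with_artifacts=False)
                _, _, _, _, f_pos, f_neg = _field_scores(params, model)
                n_pos += f_pos
                n_neg += f_neg
            n_droplets += n_pos + n_neg
            pairs.append((level, n_pos / (n_pos + n_neg)))
    r, table = gradient_report(pairs)
    return {"pearson_r": r, "levels": table, "n_droplets": n_droplets,
            "pairs": pairs}
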