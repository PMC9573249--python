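# dropvision

Image analysis for droplet digital PCR (ddPCR). A thermal-inkjet ddPCR
instrument partitions a sample into hundreds of thousands of ~32.5 µm
(24 pL) droplets, thermocycles them, and photographs the result-reading
chip field by field — one bright-field frame for localization and one
frame per fluorescence channel (Fam/Hex/Cy5) for readout. `dropvision`
turns those image pairs into droplet counts and absolute template
concentrations, for people building or validating such readouts without
vendor software.

The pipeline:

1. **Detection** (bright field): multi-threshold blob detection — the
   image is binarized at a ladder of thresholds `[T1, T1+t, …, T2]`,
   connected components are measured at every level, and detections
   that persist across levels are merged. Components are screened by
   area `A ∈ [500, 2000]` px², circularity `4πA/P²` and convexity
   `A/A_hull`, which suppresses bright spots and scratches.
2. **Vignetting correction** (fluorescence): a blurred
   uniform-fluorophore calibration frame is fitted with the quadratic
   surface `c(x,y) = a0 + a1x + a2y + a3x² + a4xy + a5y²` by least
   squares; the gain map `max(c)/c` flattens the field.
3. **Signal extraction**: each droplet's signal is the mean of the
   sorted pixel values of its disk between the 40% and 60% quantiles —
   robust to satellite droplets; dim background impurities (~50% of
   the negative level) are thresholded away.
4. **Classification**: deterministic 1-D two-means clustering splits
   positive from negative; a cluster-separation gate drops unreliable
   images.
5. **Quantification**: positive fraction `p` → mean occupancy
   `λ = −ln(1−p)` → concentration `λ/V` with `V = 24 pL`, plus
   accuracy/sensitivity/specificity against ground truth and
   concentration-gradient correlation reports.

A built-in synthetic scene generator (`dropvision.synthgen`) renders
bright-field/fluorescence pairs with exact ground truth — droplets,
vignetting, bright spots, scratches, impurities, satellites — so every
stage is testable end to end. See `docs/methods.md` for the model
details and the generator's fidelity limits.

## Worked example

```python
import numpy as np
from dropvision import (SceneParams, generate_scene, generate_flat_field,
                        radial_vignette_coeffs, fit_surface, gaussian_blur_3x3,
                        analyze_field, quantify)

coeffs = radial_vignette_coeffs(1024, 1024)          # corners at 55% brightness
scene = SceneParams(n_droplets=400, positive_fraction=0.25,
                    n_bright_spots=5, n_scratches=3,
                    vignette_coeffs=coeffs, seed=42)
bright, fluor, truth = generate_scene(scene)

flat = generate_flat_field(scene, level=10000, seed=7)  # calibration frame
model = fit_surface(gaussian_blur_3x3(flat, passes=50))

res = analyze_field(bright, fluor, vignette_model=model)
q = quantify(res.n_pos, res.n_neg, droplet_volume_pl=24.0)
print(f"detected {res.n_detected} droplets "
      f"({sum(d.cls == 'positive' for d in truth.droplets)} truly positive)")
print(f"positive {res.n_pos}, negative {res.n_neg}, "
      f"rejected {res.n_rejected}, gate pass: {res.quality_ok}")
print(f"positive fraction {q.positive_fraction:.4f}, "
      f"lambda {q.lam:.4f} copies/droplet, "
      f"{q.copies_per_ul:.0f} copies/uL")
```

prints

```
detected 400 droplets (105 truly positive)
positive 105, negative 253, rejected 42, gate pass: True
positive fraction 0.2933, lambda 0.3471 copies/droplet, 14464 copies/uL
```

All 400 synthetic droplets are found despite the injected bright spots
and scratches, and all 105 true positives are labeled positive. The 42
"rejected" droplets are the impurity gate clipping the low tail of the
noisy negative population (see `docs/methods.md`, signal section); the
measured positive fraction is computed over classified droplets, and
λ and the concentration follow from Poisson statistics at 24 pL per
droplet.

## Command line

```sh
dropvision simulate --config scene.yaml --out sim/ --seed 1 --n-fields 3
dropvision detect --image sim/field000_bf.tif --out droplets.csv
dropvision fit-vignette --template calibration.tif --out model.json
dropvision correct --image sim/field000_fl.tif --model model.json --out flat.tif
dropvision classify --droplets droplets.csv --fluorescence sim/field000_fl.tif \
    --model model.json --out labeled.csv
dropvision run --config run.yaml      # full multi-field pipeline
dropvision quantify --n-pos 1200 --n-neg 8800
```

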