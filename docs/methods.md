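# Methods

`dropvision` implements the image-analysis half of a droplet digital PCR
(ddPCR) readout: tens of thousands of ~32.5 µm (24 pL) droplets are held
in a monolayer in a result-reading chip and photographed field by field,
once in bright field and once per fluorescence channel. The bright-field
frame is used only to find and localize droplets; the fluorescence frame
supplies each droplet's signal; counting bright (positive) versus dim
(negative) droplets gives absolute template quantification through
Poisson statistics.

## Droplet detection (bright field)

Droplets appear as bright rims with a distinct interior level. The
detector binarizes the image at a ladder of thresholds
`[T1, T1+t, T1+2t, …, T2]` (defaults 40…220, step 10, for an 8-bit
bright field), extracts 8-connected components at every level, and
measures each component:

* **center** — centroid of the filled pixels (sub-pixel stable);
* **area** — pixel count;
* **perimeter** — 4-direction Crofton estimate, computed per component
  by attributing each 2×2 pixel configuration to the component that
  owns it. The Crofton estimator is close to unbiased for smooth
  digitized shapes; a naive boundary trace overestimates a disk's
  perimeter by ~5%, which would push the circularity of a perfect
  digitized disk down to ~0.9 and make a screen that presumes "disk ≈
  1" systematically unfair;
* **convex-hull area** — exact hull of the pixel region, from the
  corner points of the boundary pixels.

Candidates are screened **per level** by the area window
(default [500, 2000] px², matching droplets of radius ~12.6–25.2 px),
circularity `4πA/P²` (default ≥ 0.7) and convexity `A/A_hull` (default
≥ 0.85). Per-level screening matters: at thresholds above the interior
gray level only the rim survives as a low-circularity annulus sharing
the droplet's center, and without screening it would join the droplet's
cross-level group and poison the averaged shape statistics.

Surviving candidates whose centers agree within a grouping radius
(default 4 px) across levels are merged; a group must appear in at
least `min_repeatability` (default 2) levels. Reported center and size
are group means, re-screened once more. Oversized/undersized bright
spots fail the area window; scratches fail circularity; both disappear
from the droplet list without any dedicated artifact model. Droplets
whose bounding circle touches the frame are flagged `edge_flag` and
excluded from counting (incomplete droplets at the image edge are not
countable).

The ladder bounds, step, repeatability and grouping radius are
calibration constants, not derivable from first principles; they are
exposed in `DetectorParams` and were chosen for an 8-bit bright field
with background ≈ 95 and droplet interior ≈ 145.

## Vignetting correction (fluorescence)

The optics attenuate the frame toward its edges, which shifts edge
droplets' signals down and smears the two signal populations together.
A droplet-free view of the correction: a uniform-fluorophore
calibration frame is blurred with repeated 3×3 binomial passes
(kernel (1,2,1;2,4,2;1,2,1)/16, default 50 passes ≈ Gaussian σ≈7 px —
a single 3×3 pass cannot erase droplet-scale texture from a full
frame), and the blurred template is fitted with the quadratic surface

    c(x, y) = a0 + a1·x + a2·y + a3·x² + a4·x·y + a5·y²

by QR-based linear least squares on a stride-8 sample grid. The gain
map is `max(c)/c`, with the maximum taken at the analytic stationary
point when it is an interior maximum, otherwise at the grid maximum;
the map is re-normalized so its minimum is exactly 1 (the brightest
point is left untouched, edges are brightened) and clamped at 10 to
stop extrapolated corner blow-ups. Models serialize to JSON so one
calibration per channel serves all fields of a run.

Uniformity is scored by partitioning the image into a 3×3 grid and
averaging (center-tile mean − edge-tile mean) over the eight edge
tiles; on synthetic vignetted flat fields correction reduces this
statistic by ≥ 85% (typically ≈ 99%).

## Signal extraction and impurity suppression

The signal of a droplet is the mean of the sorted pixel values of its
sampling disk between the 40% and 60% quantiles (`[⌊0.4n⌋, ⌈0.6n⌉)`,
never empty). This inter-quantile mean has zero breakdown against the
two contamination modes the generator reproduces: saturated satellite
pixels sort above the retained band, and background pixels swept in
when a fused satellite distorts the detected outline sort below it.

Background impurities (autofluorescent debris at roughly half the
negative-droplet level) are removed by thresholding the signals before
classification. The default threshold is `0.75 ×` a provisional
negative level, taken as the 25th percentile of the signal
distribution — a robust stand-in for the negative-cluster center that
is available before clustering has run. **Limitation:** under the
benchmark noise (per-droplet intensity scatter of 5% of the class
separation, i.e. 25% of the negative mean) the impurity band lies only
~2σ below the negatives, so this gate also clips ~5–10% of the
negative tail even in impurity-free images. Those droplets are
reported as `rejected` (the per-field conservation
`n_pos + n_neg + n_rejected + n_edge = n_detected` always holds), and
classification accuracy is defined over droplets assigned a
positive/negative label. The clipping also biases measured positive
fractions upward by ~1–3 points; the bias is monotone across
concentrations and leaves gradient correlations at ≈ 0.9999. With a
tighter intensity scatter (≤10% of the negative level) the gate
separates impurities from negatives cleanly.

## Classification and quality gate

Signals are split positive/negative by two-means clustering. In 1-D
the optimal 2-means partition is a threshold on the sorted values, so
Lloyd iteration from the deterministic (min, max) initialization is
reproducible and matches the exhaustive threshold-scan optimum in the
bimodal regime the assay operates in; seeded random restarts are
available but off by default. Ties go to the negative cluster. A
quality gate rejects images whose cluster separation is below
`min_separation` (default 4 × the pooled within-cluster standard
deviation), which fails single-population fields whose "separation" is
pure noise; gated fields are excluded from pooled quantification.
Clustering is per image by default, with a pooled mode
(`pool_signals`) that clusters all fields of a channel jointly.

## Quantification and evaluation

For positive fraction `p`, mean occupancy is `λ = −ln(1 − p)` and
concentration `λ / V` with droplet volume V = 24 pL (reported both per
pL and per µL). Saturated samples (no negatives) raise instead of
returning a pseudo-value. Evaluation metrics follow the standard
confusion-matrix definitions — accuracy `(TP+TN)/total`, sensitivity
`TP/(TP+FN)`, specificity `TN/(FP+TN)` — with undefined ratios
returned as `None`, never as 0. Detections are matched to ground truth
greedily by nearest center within a tolerance (2 px for benchmark
scoring), each point used once.

## The synthetic generator

`synthgen` renders matched bright-field/fluorescence pairs with exact
ground truth. What it emulates: rim-rendered droplets (8-bit bright
field, background 95 / interior 145 / rim 230, rim 2 px) whose area
distribution sits inside the [500, 2000] px² screen (radius 16 ± 1 px);
two fluorescence classes at 2000/12000 gray (16-bit) with per-droplet
scatter of 5% of the separation; quadratic radial vignetting (corner
level 0.55); additive Gaussian noise clipped to the gray range;
oversized and undersized bright spots; thin bright scratches; dim
impurities at 50% of the negative mean rendered droplet-like in bright
field; and satellite droplets (radius 3–5 px at 0.9–1.1 parent radii,
parent intensity) that fuse with their parent's bright-field component
and sweep background pixels into the sampling disk. Placement is
seeded random sequential adsorption with a 3 px clearance (touching
anti-aliased rims would fuse components; the detector deliberately has
no watershed splitting) and bounded retries — an infeasible density
raises instead of looping. Artifacts are placed first and droplets
avoid them, so artifact suppression is tested as a false-positive
problem, not an occlusion problem.

What it does **not** emulate — and what passing benchmarks therefore
do not show: defocus/PSF blur, Poisson shot noise, spectral crosstalk
between channels, droplet crowding with true rim contact, drifting
illumination between calibration and acquisition, and misregistration
between bright-field and fluorescence frames (the stages share one
coordinate frame here; a real instrument must guarantee this
optically).

## Benchmark problem sizes and numerical choices

Benchmark fields are 2048×2048 px with 1700 droplets (the per-image
droplet load of a real chip; 1700 droplets of radius 16 px cannot fit
in a 1024² frame, which caps feasible packing near ~550). The headline
checks use 20 such fields for detection/classification and a
four-level gradient (positive fractions 44.44/27.50/17.18/10.72%) with
four replicates of ~10,200 droplets each. Degenerate inputs fail loud:
empty ladders, under-determined or non-positive surface fits, empty
sampling disks, all-identical signals and saturated counts all raise
`ValueError`/`RuntimeError` with specific messages. Circularity is
clipped at 1 to absorb discretization overshoot; convex-hull area is
floored at the pixel area; the trimmed slice always keeps at least one
element.
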