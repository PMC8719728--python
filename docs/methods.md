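# Methods

## The model

`wbcseg` segments leukocyte nuclei by chromatic outlierness.  Color is
treated as a two-part quantity: chromaticity (hue) and brightness.  In a
stained smear nearly every pixel — background, red cells, platelets —
shares one family of pale warm hues, while WBC nuclei sit far away in
the purple-violet band.  The pipeline makes that separation explicit in
two PCA stages.

**Stage 1 (hue decorrelation).**  Per-pixel hue 2-vectors (Lab: the
(a\*, b\*) opponent coordinates; HSV: the unit vector (cos h, sin h))
are centered and projected onto their principal axes.  The projection
is a rigid rotation of the hue plane; it removes the field's mean hue
so that the subsequent substitution expresses every pixel's hue as a
*deviation from the average* — the quantity a human effectively sees.

**Stage 2 (chromatic contrast).**  The hue-substituted image is mapped
back to RGB and every pixel normalized to a unit vector, discarding
brightness.  A 3-D PCA on these unit vectors finds the axis along which
chromatic deviation is largest; the scalar projection ω of each pixel
onto that axis is the enhancement map.  Because WBC pixels are the
chromatic outliers, |ω| is large exactly on nuclei.

**Axis selection.**  The projecting eigenvector is the top one when its
variance fraction reaches δλ (0.9 in Lab, 0.75 in RGB/HSV), else the
second.  The rule is implemented on variance *fractions*, so it is
independent of eigenvalue ordering conventions; this package stores
eigenvalues descending, with eigenvector signs fixed by making each
vector's largest-magnitude entry positive (removes eigensolver sign
nondeterminism).  A chromatically uniform image has no outlier axis and
raises a typed `DegenerateModelError` rather than returning noise.

**RGB mode.**  RGB has no native 2-D hue; in this mode the first stage
is skipped and the second PCA runs directly on the normalized RGB
vectors (normalization removes intensity, leaving chromatic direction).
This reading is kept configurable because it is an interpretation, not
a definition.

## From ω to a count

- **Binarization.**  |ω| is min-max rescaled to [0, 255] per image and
  thresholded at δω = 37 (inclusive).  The rescale is deliberate: with
  unit color vectors raw |ω| ≤ 2, so an 8-bit-scale threshold is only
  meaningful after rescaling.  This is the largest single inference in
  the implementation and is therefore stated prominently here.
- **Small-object removal.**  Components strictly smaller than the area
  cutoff are deleted (a component exactly at the cutoff survives).
  Cutoffs are 3500 px for 1368×1712 images and 5000 px for 1944×2592
  images; by default the configured cutoff auto-scales linearly with
  image area relative to `reference_area_px`, and both literal pairs are
  available as presets (`allidb-small`, `allidb-large`).
- **Border detection.**  A pixel is a border when the Prewitt gradient
  magnitude of ω (normalized to [0, 1]; classical ±1 masks, magnitude
  √(Gx²+Gy²)) exceeds δI = 0.2 AND the angular differences
  θx = arccos(φ̂\*(i,j)·φ̂\*(i+1,j)) and θy = arccos(φ̂\*(i,j)·φ̂\*(i,j+1))
  both exceed δθ = 2.5°.  Dot products are clipped to [−1, 1] before
  arccos; the last row/column use the clamped neighbor (angle 0).  The
  conjunction is the default reading; a config switch (`border_combine:
  or`) enables the disjunctive variant for sensitivity analysis.  Note a
  structural property of the conjunctive rule: across an ideal 1-px step
  edge the angle in the edge's own direction is exactly zero, so the
  rule can only mark transitions that vary in both grid directions —
  i.e. real (blurred, textured) edges, not synthetic hard steps.  The
  unit tests pin this down.
- **Overlap separation.**  Border pixels are erased only inside
  components larger than the separation cutoff (13,000 / 21,000 px).
  Because the detected border band lies partly inside a cell, erasing
  it can shave thin "skin" slivers off a component; fragments smaller
  than the small-object cutoff are therefore discarded during
  relabeling (the largest fragment is always kept).  Separation never
  increases foreground area and never decreases the component count.
- **Counting.**  8-connected component labeling.  Counting precision
  Cp = N/M·100 adjudicates "correctly detected" by greedy
  maximal-overlap one-to-one matching between detected components and
  ground-truth cells, requiring the overlap to cover at least half of
  the smaller object.  With no detections Cp is undefined and reported
  as `None`, never as 0.

## Evaluation metrics

Pixel metrics follow the standard confusion-table formulas; kappa is
(Ac − t)/(1 − t) with t the chance agreement of the marginals, banded as
poor (≤0.2), reasonable (≤0.4), good (≤0.6), very good (≤0.8),
excellent (>0.8).  Metrics with vanishing denominators are reported as
`None` so set averages can skip them.  For partition metrics with a
single ground truth, the probabilistic Rand index reduces to the plain
Rand index (pair-agreement fraction); VOI uses the natural logarithm by
default (the base is a constant factor, exposed as an option); GCE is
computed from the contingency table as the smaller of the two directed
refinement errors.  Pixel metrics are computed over the full image; if
a ground truth includes cytoplasm while the pipeline segments only
nuclei, sensitivity will be depressed accordingly — this is documented
behavior, not corrected.  Batch evaluation offers both per-image
averaging and pooled counting.

## The synthetic-smear generator

`wbcseg.synthetic` renders the study conditions: 8-bit RGB smears at
the two reference sizes with exact per-cell ground truth.  Defaults
(frozen once, used by tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| WBC hue | 280° ± 10° (HSV degrees) | purple-violet nuclear stain band |
| WBC saturation / value | 0.66 / 0.45 | dark saturated nuclei |
| WBC radius | 58 ± 4 px (small), 70 ± 4 px (large) | nucleus size; clipped to [0.78, 1.18]·mean so singles stay between the deletion and separation cutoffs |
| RBC hue / sat / val | 348° ± 3° / 0.12 / 0.88 | pale pink discs with central pallor |
| background | hue 348°, sat 0.07, val 0.92 | stain-tinted bright field with an 8% illumination gradient |
| chromatin texture | hue jitter σ = 6°, brightness speckle 5% | per-pixel granularity |
| PSF blur | σ = 1.2 px | optical point-spread |
| sensor noise | σ = 3.5 (8-bit counts) | additive Gaussian, post-blur |
| cells per image | 6 (small), 10 (large) | typical field occupancy |

The background is rendered in the same warm pink family as the red
cells because stained-smear backgrounds carry stain residue; this makes
field chromaticity essentially one-dimensional (pink ↔ purple), which
is precisely the premise of the enhancement — the WBC hue contrasts
with the *average* hue.  Under these defaults the top-axis variance
fraction sits near 0.98, far from the 0.9 selection threshold.

**Overlap optics.**  A deliberately fused pair is rendered with three
features of real overlapping nuclei: the two cells stain slightly
differently (hues drawn from opposite halves of the band, distinct
brightness); the overlap lens accumulates stain (deeper hue, darker,
strongly textured); and a dark, *desaturated* contact seam (saturation
×0.2, brightness ×0.3, half-width 5 px) runs where the dense periphery
of each nucleus crosses the other.  The seam matters mechanically: its
desaturation swings the normalized chromatic direction back toward the
field average, carving a valley in ω whose flanks carry the strong
gradient the border operator thresholds, and being the darkest
structure it carries the largest angular sensor noise, which keeps both
angular conditions alive where the seam runs parallel to the pixel
grid.  Ground-truth masks are the exact pre-noise geometric coverage of
each nucleus (no anti-aliasing leakage); overlapping cells keep
distinct label ids, with the later cell overwriting the earlier where
they intersect, as the upper cell does optically.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: cytoplasm around nuclei (real ground
truths often include it, depressing sensitivity), platelets and debris,
uneven staining gradients within a cell, clumps of more than two
overlapping nuclei, JPEG artifacts, and the full morphological
diversity of leukocyte types.  Results on the synthetic suites
demonstrate correctness of the operators under the stated model, not
clinical performance.

## Numerical choices

- Color conversions delegate to scikit-image (sRGB companding, D65
  white point); hue is held in radians in [0, 2π); gray pixels take hue
  0 by convention; out-of-gamut Lab values are clamped channel-wise at
  the final RGB mapping only, so PCA always operates on unclamped
  values.
- Covariance uses population (1/n) normalization; only variance
  fractions enter the axis-selection rule, so the choice is inert
  there, but it is fixed for reproducibility.
- The piecewise quadrant arctangent returns 0 on the positive x-axis, π
  on the negative x-axis and 0 at the origin (flagged degenerate); it
  agrees with a full-circle arctangent oracle to 1e-12 everywhere else.
- The segmentation path is fully deterministic; the only randomness in
  the package is the generator's, behind explicit integer seeds.

## Problem sizes

The test suite runs unit tests on down-scaled smears (342×428, radii
shrunk by the same factor as the image so the auto-scaled cutoffs are
consistent) and the end-to-end checks on 20 full-size images (10 per
size preset) plus 10 fused-pair images.  The acceptance script uses 8
no-overlap images per preset and 10 fused-pair images per run; these
sizes give stable rates while keeping a full run within a few minutes
on one CPU.

## Known limitations

- The per-image min-max rescale of |ω| ties the δω threshold to the
  brightest chromatic outlier; an image whose strongest outlier is an
  artifact would shift the effective threshold.
- The conjunctive border rule cannot cut overlap junctions that are
  perfectly straight, noise-free and axis-aligned (see above); real and
  rendered junctions are neither.
- Auto-scaling the area cutoffs linearly with image area reproduces the
  two published preset pairs only approximately (their ratios differ:
  ≈1.43 for deletion vs ≈1.62 for separation against an area ratio of
  ≈2.15); the literal presets are provided for exact reproduction.
- PRI with a single ground truth is the plain Rand index; with multiple
  annotators it would not reduce this way.
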