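# Methods

## Scope and model

`rosettephen` quantifies single rosettes in top-view RGB images from a
per-pixel semantic segmentation with leaf states.  Three class schemes are
supported:

| scheme | classes (label) |
|---|---|
| A | background (0), class_norm (1) |
| B | background (0), class_norm (1), class_senesc (2) |
| C | background (0), class_norm (1), class_antho (2), class_senesc (3) |

`class_norm` is green/healthy tissue, `class_antho` anthocyanin-rich
(red/purple) tissue, `class_senesc` senescent/dead tissue.  The compound
`plant_region` is the union of `class_norm` and `class_antho` — the living
plant excluding senescent area; for schemes A and B it coincides with
`class_norm` but its columns are always emitted so the table schema is
stable across schemes.  Labels are consecutive integers from 0 in the listed
order; masks are 8-bit single-channel PNG; coordinates are 0-based,
row-major, origin top-left.

Coarsening merges vocabularies: C→B folds `class_antho` into `class_norm`;
C→A and B→A additionally map `class_senesc` to background, because the
one-class vocabulary carries no senescence concept.  Coarsening conserves
pixel counts exactly and composes (C→A equals C→B→A pixelwise).

## Traits

Each class block of a results row carries 19 traits.  All pixels of a class
are treated as **one region even when disconnected** — hull, bounding box
and ellipse moments describe the whole rosette, not individual leaves.

Morphometric (11): `area`, `filled_area` (holes filled with 4-connected
background, complementing 8-connected foreground), `convex_area`,
`equivalent_diameter` = sqrt(4·area/π), `major_axis_length` and
`minor_axis_length` (axes of the ellipse with the same normalized second
central moments as the pixel set: 4·sqrt(λ₁), 4·sqrt(λ₂)), `perimeter`
(weighted contour steps, 1 for straight and √2 for diagonal moves),
`eccentricity` = sqrt(1 − λ₂/λ₁), `extent` = area / bounding-box area,
`solidity` = area / convex_area, `aspect_ratio` = major/minor.  The convex
hull is taken over pixel centers and `convex_area` counts pixel centers on
or inside it; for degenerate (single-pixel or collinear) regions every
pixel center lies on the hull segment, so `convex_area` equals `area`.
Moments, perimeter, extent and ellipse quantities delegate to
scikit-image's `regionprops`; the hull uses
`convex_hull_image(offset_coordinates=False)` so that the pixel-center
definition holds exactly.

Color (3 + 5): per-class mean R, G, B intensities of the original image,
then five chroma indices computed **from the per-region means** (not
averaged per-pixel indices): chroma_base = (N_b+N_r)/N_g,
chroma_difference = (N_b+N_r)/2 − N_g, chroma_ratio = N_g/((N_b+N_r)/2),
blue_green_ratio = N_b/N_g, green_strength = N_g/(N_r+N_g+N_b).  The chroma
ratio is inversely related to anthocyanin pigmentation.  Identity:
chroma_ratio · chroma_base = 2 whenever both are defined.

Missing-value policy: an absent class yields area 0 and every other field
missing (NaN, empty in CSV), distinguishing "class not present" from
degenerate geometry; any index with a zero denominator is likewise missing,
never infinite.

A scheme-C row holds 4 class blocks × 19 traits + `total_area` (all
non-background pixels) + `background_area` = **78 trait columns** plus the
image identifier; scheme B gives 59, scheme A 40 (19·(n_classes) + 2 with
the plant_region block included).

## Baseline segmentation

The classical comparator converts sRGB to CIELAB (D65) and labels a pixel
plant iff a* ≤ `a_max` and L* ≥ `l_min`, then keeps the largest 8-connected
component and fills holes.  Defaults: `a_max = −3`, `l_min = 15`.  The a*
threshold sits just below the achromatic axis: on the synthetic fixtures the
green-leaf a* distribution is centered near −35 with an upper tail reaching
about −5, while soil, gray and blue-mesh backgrounds sit near or above 0.
A stricter cut (e.g. −8) intersects the leaf tail and occasionally discards
entire yellowish-green leaves — a large, unrecoverable IoU loss — whereas
the scattered sub-threshold soil pixels admitted at −3 are isolated specks
that the largest-component cleanup removes.  A sweep over 100 synthetic
scene pairs gave minimum green-rosette IoU 0.977 and maximum
anthocyanin-rosette IoU 0.0 at −3.  Both thresholds are exposed as CLI
flags.  By construction the baseline fails on anthocyanin-rich plants
(a* ≫ 0): this failure mode is kept as a regression contrast, not patched.

`multiscale_predict` wraps any pixel classifier returning per-class scores:
bilinear resize of the image to each scale factor (default {0.5, 0.75, 1.0,
1.25, 1.5, 1.75}), classify, bilinear resize of scores back, per-pixel mean,
renormalization, argmax.  Bilinear interpolation is linear, so
simplex-valued score fields stay normalized up to float error; the explicit
renormalization makes the contract exact.  No network inference is bundled;
the classifier callable is the extension point.

## Evaluation

mIoU = mean over classes of TP/(TP+FP+FN) with TP/FP/FN pooled over all
evaluated images (pooled-pixel convention, not per-image averaging).
Background counts as a class; classes with TP+FP+FN = 0 are excluded from
the mean to avoid 0/0.  Inter-scheme area agreement is the R² of an
ordinary least-squares fit on untransformed pixel areas, intercept
included.

## Synthetic scenes

`generate_rosette` places `leaf_count` elliptical leaves radially
(angle 2πl/leaf_count + Gaussian jitter, sd 0.15 rad), leaf base at the
image center, length ~ N(48, 10) px and width ~ N(18, 4) px on the default
256×256 grid (floors 4 and 2 px).  Each leaf draws a state from
`state_probabilities` and a single color from that state's distribution:
green (45,110,40), anthocyanin (95,40,85), senescent (150,120,60), ±15 per
channel — package conventions chosen for plausible green/purple/brown
separations.  Leaves are drawn back to front and the mask is rasterized
from the same geometry in the same order, so labels match visible pixels
exactly and per-class pixel counts are exact ground truth.  Backgrounds:
solid gray; blue mesh (periodic blue grid lines over dark gray, emulating
blue plastic tray meshes); soil (brown base with per-pixel Gaussian grain,
sd 8); soil with algae (sparse green dots that a color threshold
misclassifies — deliberately, as a known hazard of color-based
segmentation; the cleanup step removes them).

Each scene uses one pseudo-random stream seeded by `(seed, index)`
(`numpy` `default_rng([seed, index])`), so scenes are reproducible
independent of generation order.  `generate_time_series` adds one leaf per
age step and takes a caller-supplied monotone mapping age → state
probabilities; trend studies here use a full-range linear ramp
p_senesc = age/9 over 10 ages (0 → 1, with a small anthocyanin share),
emulating a canopy that senesces completely by the end of a long
experiment.  With per-leaf state draws and 6–15 leaves per scene, shallower
ramps leave the per-scene senescent fraction dominated by binomial noise;
the full ramp keeps the pooled age-vs-fraction Spearman correlation above
0.9 at 10 ages × 20 replicates.

What the generator does **not** emulate: perspective and lens distortion,
shadows and specular highlights, leaf texture/venation, 3-D occlusion by
neighboring plants, and non-elliptical leaf shapes.  Passing tests
therefore validate the trait arithmetic, schema contracts and the
qualitative color-baseline behavior — not segmentation accuracy on real
phenotyping imagery.

## Pipeline

Inputs are scattered into ceil(N/batch_size) lexicographically ordered
batches (default batch size 10); batches are independent work units and the
gather step restores input order, so batch size never changes a value.
Images pair with masks by file stem; a missing mask is an error, not a
silent drop.  Per-image failures are collected, the run continues, and a
strict run (default) exits nonzero at the end.  The results table is UTF-8
CSV with missing values as empty fields; identical inputs and configuration
yield byte-identical files.  Diagnostics per image: class-color overlay at
alpha 0.5 (green/magenta/gold for norm/antho/senesc), color-coded mask,
background-subtracted crop of `plant_region` (original pixel values inside
the region, zero outside, cropped to its bounding box), and a convex-hull
outline panel.

## Problem sizes and numerical choices

Tests and the acceptance script run on 256×256 scenes: oracle suites use 50
random shapes and 100 random 16×16 mask pairs; the chroma identity is
checked on 10,000 random triples (tolerance 1e-9); the trend study uses 10
ages × 20 replicates; determinism is checked over 100 images at two batch
sizes.  These sizes give stable statistics (trend ρ ≈ 0.92–0.94 across
seeds) while keeping the full suite under a minute.  Ties in the
score-argmax resolve to the lowest label (numpy argmax convention).

## Known limitations

- The 19-trait-per-class inventory completes the documented 78-column
  schema, but per-class trait naming beyond the explicitly defined set
  (area, equivalent diameter, ellipse axes, convex hull, solidity, extent)
  is a repository convention.
- The Lab-threshold baseline is a faithful stand-in for classical
  color-based segmentation, not a reimplementation of any proprietary
  product pipeline.
- mIoU figures of trained neural segmentation models are out of scope; the
  evaluation module scores any predicted masks supplied to it.
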