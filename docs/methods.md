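# Methods

`octlumen` segments the inner lumen surface of a tubular organ — the
motivating application is the rat trachea — from rotational endoscopic
OCT pullback stacks, and quantifies cross-sectional areas and total
lumen volume. This note records the model, its assumptions, the
parameter choices, and the limits of what the bundled synthetic phantoms
can demonstrate.

## Image model and coordinate conventions

A pullback stack is an ordered set of polar B-scans. Each B-scan has
rows = depth samples along an A-line (index `j`, 0 nearest the probe)
and columns = angular A-line positions (index `i`). Intensities are
normalized to [0, 1] at load time (integer input divided by the dtype
maximum, floating input by the stack maximum), so every threshold in the
pipeline is bit-depth independent.

Physical mapping: `radius(j) = probe_offset_radius + j * radial_pixel_pitch`,
`theta(i) = 2*pi*i/W`, `z(frame) = frame * frame_spacing`, with
`frame_spacing = pullback_speed / frame_rate`. The default fixture
geometry uses 0.01 mm/px radial pitch and a 0.3 mm probe offset
(a 0.4 mm probe inside a 0.6 mm OD sheath), and a 5 mm/s pullback at
25 fps (1,500 rpm, one frame per revolution), i.e. 0.2 mm between
frames; 150 frames span 3 cm.

## Segmentation pipeline

Per frame, three stages:

1. **De-noising.** A square median filter (default 5×5; ≈ the 34 µm
   lateral resolution scale at the fixture pitch) suppresses speckle.
   Border handling is reflect in depth and wrap across columns, because
   the angular direction is circular. Then each A-line is scaled so its
   intensity sum equals the mean column sum of the frame, flattening
   bright sheath-reflection A-lines while preserving overall brightness
   (zero-sum A-lines are left unscaled and logged). Median first, then
   normalization. The result is rescaled to unit maximum.
2. **Feature extraction.** Otsu binarization (the lumen/tissue histogram
   is close to bimodal) with the top `sheath_exclusion_depth` rows
   (default 10) forced to background — a fixed guard band for the sheath
   rings, in addition to small-object removal. Foreground components
   below `min_object_area` pixels (default 200) are removed with
   8-connectivity that wraps across the angular seam. For each A-line,
   everything deeper than `surface_margin` pixels (default 30 ≈ the
   0.3 mm tissue-band scale) below the first foreground pixel is zeroed,
   so deeper interfaces (detached layers, far wall) cannot attract the
   tracer; masking zeroes rather than attenuates — the strongest form of
   de-emphasis. A-lines with no foreground are reported and left
   unmasked. Finally the rising-edge depth derivative
   `G[j] = max(I[j] - I[j-1], 0)` (row 0 set to 0), rescaled to [0, 1],
   turns the dark-to-bright lumen/tissue transition into a bright ridge.
   The derivative is placed on the *first bright* pixel so the traced
   row is exactly the depth index the radius map assigns to the tissue
   surface; falling edges are clipped so the far side of the tissue band
   stays dark.
3. **Edge detection.** The boundary is the minimum-cost one-row-per-
   column path through the gradient image. Transition cost
   `w(a, b) = 2*max(I) - a - b`; diagonal moves are scaled by `alpha`
   (default √2, the geometric step-length ratio; exposed in config).
   Accumulated costs are filled left to right, seeded at column 0 with
   `2*(max(I) - I(0, j))` — bright pixels are favoured without biasing
   any row. Ties between predecessors break straight, then up, then
   down (deterministic, favours smooth boundaries). Traceback starts at
   the minimum of the last column (smallest row on ties). Because the
   B-scan is cylindrical, the image is duplicated and concatenated at
   both ends ([G|G|G]), the tracer runs on the triple-width image and
   the middle copy is returned; the `closed` flag records whether the
   two seam ends meet within one row. Boundary rows at the image borders
   are allowed (the predecessor set is clamped).

## Quantification

The traced boundary maps to a Cartesian polygon (one vertex per
A-line); the cross-sectional area is its shoelace area — exact for
polygonal boundaries and resolution independent. Areas are measured
from the rotation axis, so the sheath cross-section is included: it
occupies lumen space. Volume is the rectangle rule, sum of areas times
frame spacing, matching the voxel semantics of a stacked binary
reconstruction (a polar lumen mask per frame is exported for that
purpose). Mean/SD use the sample (n−1) denominator. Regional summaries
are computed over contiguous fractions of the pullback, default a
proximal/distal split at 0.5. Frames whose detection fails are flagged,
excluded from volume/mean/SD and counted; a run aborts if more than 20%
of frames fail. Frames are processed independently — no temporal
smoothing.

## Agreement analysis

Bland–Altman between two frame-aligned area series: differences A−B
against means (A+B)/2, bias = mean difference, 95% limits of agreement
= bias ± 1.96·SD(diff) (fixed normal multiplier; at ~150 frames the
small-sample t correction is negligible). The bias is also reported as
a percentage of the grand mean of the per-frame means — the
conventional normalization for a relative systematic error.

## Synthetic phantom

The phantom emulates: a dark lumen around the probe, a bright tissue
band starting at a known radius profile `r(theta, z)` with exponential
depth attenuation, bright sheath rings at fixed shallow rows,
multiplicative gamma speckle with mean 1 (shape 4 ≈ heavily speckled
but median-filterable), and additive Gaussian background noise. Presets:
cylinder, ellipse, focal stenosis (Gaussian axial dip; a 0.5 narrowing
quarters the area), and a raised-cosine tissue flap bulging into the
lumen. Defaults: 150 frames, 256 A-lines, 180 depth rows, cylinder
radius 1.2 mm (2.4 mm lumen diameter, at the small-animal airway
scale), tissue thickness 0.3 mm, reflectivity 0.8, attenuation 2 /mm.
Ground truth stores the exact surface rows, the analytic polar areas
`(1/2)∮r² dθ` evaluated at the A-line sampling, the analytic volume and
the noise-free tissue mask — an oracle sharing no code with the
segmentation path. Identical spec and seed give a bit-identical stack.

What the phantom does *not* emulate: the OCT point-spread function and
sensitivity roll-off, non-uniform rotational distortion, secondary
(false) lumens, luminal debris and fluid, and motion. Passing the
phantom checks therefore demonstrates the correctness of the algorithm
and its geometry handling, not clinical-grade robustness on injured
airways.

## Numerical choices and degenerate inputs

- Constant frames have no Otsu threshold: binarization returns an empty
  mask with a warning; the frame is then flagged as failed downstream.
- An empty binary mask leaves the frame unmasked (warning) rather than
  erasing it.
- Zero-sum A-lines are not normalized (no division by zero).
- DP oracle equivalence is asserted to 1e-9 absolute (summation-order
  float differences between recursion and enumeration).
- The path model is one row per column with ±1-row steps: surfaces
  steeper than one depth pixel per A-line (near-vertical walls,
  overhanging flaps) cannot be followed. The flap preset default
  (0.15 mm lift over a quarter turn) respects that limit by design.
- Stenosis tests place the narrowing center exactly on a frame
  (z fraction grid is `k/(n_frames-1)`).

## Problem sizes used in the checks

The bundled checks run the full pipeline on 150-frame pullbacks
(256 A-lines × 180 depth rows) — the fixture pullback scale — and the
tracer-optimality check enumerates all admissible paths on 200 random
gradient images up to 8×12, where exhaustive enumeration is exact and
cheap. Unit tests use 10–31-frame stacks of the same frame size.
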