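# Methods

This note documents the models and procedures implemented in
`aquacolor`, the parameter defaults and why they were chosen, what the
synthetic-scene generator does and does not emulate, and the numerical
and design choices made where the method left room.

## Color spaces

All correction happens in CIE Lab. The forward path scales 8-bit RGB
to [0, 1] and applies the fixed matrix

```
X   0.412453 0.357580 0.180423   R
Y = 0.212671 0.715160 0.072169 · G
Z   0.019334 0.119193 0.950227   B
```

followed by the Lab compression `f(v) = v^(1/3)` for `v > 0.008856` and
the linear branch `7.787037·v + 16/116` below, against the white point
`(0.9515, 1.0, 1.0886)`. Lightness is the standard `L = 116·f(Y/Yn) −
16`, so black maps to `L = 0` and the reference-white luminance to `L =
100`. No gamma linearization is applied before the matrix; the pipeline
only requires that its forward and inverse transforms agree, and the
inverse (branch selected at `f(0.008856) = 0.206897`, final clamp to
[0, 255]) round-trips every 8-bit color to within one intensity level.
This is a device-model choice, not an ICC-grade colorimetric pipeline
(a stated non-goal).

## Checkerboard localization

The board is a 4×6 grid of 24 reference colors inside a 200×200-px
canonical region of interest, with an ArUco-style fiducial at each
corner. The fiducial system is self-contained: a deterministic
dictionary of 50 codes on a 4×4 payload grid (6×6 modules with the
black border), generated so that every code is at Hamming distance ≥ 4
from every rotation of every other code and from its own rotations.
Detection binarizes with Otsu's threshold, fits convex quadrilaterals
to dark connected components (polygon simplification plus a
line-fit/intersection corner refinement), oversamples the module grid
10× through a projective transform with a small grid-offset search, and
majority-votes each module. Up to one payload bit-error is accepted —
safe, since Hamming-1 balls around dictionary codes are disjoint.

The image→ROI homography is a least-squares direct linear transform on
all detected marker corners (16 points when all four markers are seen;
4 well-spread points suffice). Block colors are the mean RGB over the
central 50% × 50% window of each warped cell — the margin guards
against bleed at cell borders, which the method itself does not
specify. Grid order is row-major reading order; the marker-id→corner
assignment is a package convention shared by the detector and the
synthetic renderer and recorded in the layout config.

## Correction model

The model is a single 3×3 matrix `M` acting on Lab column vectors —
deliberately linear with no affine offset, mirroring the published
formulation even though an offset often fits residual cast better. With
24 block pairs the stacked system has 72 equations in 9 unknowns; for
any noise-free invertible linear distortion it is consistent, so least
squares recovers the exact inverse (the acceptance suite demands
max-entry error < 1e−6 over 100 random distortions). The reported
`residual` is the root-mean-square Lab error over the 24 blocks after
correction — a quality diagnostic the method displays but never defines;
RMS is our choice. Rank deficiency (e.g. all blocks measuring the same
color) raises an estimation error naming the deficiency rather than
returning a garbage matrix. Pixels are corrected fully vectorized;
gamut clamping happens only at the final Lab→RGB step.

One practical caveat documented here because it shapes test design:
if the scene distortion pushes a reference color out of the RGB gamut,
clipping breaks linearity and exact recovery no longer holds. The
generator's default distortion was chosen to keep all 24 reference
colors in gamut for exactly this reason.

## Fuzzy candidate extraction

Antecedent 1 is the patch's minimum Euclidean distance `p1` (pixels) to
any foam contour; antecedent 2 is the population standard deviation
`p2` of its BT.601 gray levels (divisor `w·w`, not `w·w − 1`). Each
variable carries five linguistic sets (VS, S, M, L, VL) with peaks at
`(0, 25, 50, 75, 100)` px for `p1` and `(0, 45, 90, 135, 180)` gray
levels for `p2`: interior sets are triangles spanning adjacent peaks,
the outer sets are shoulders (grade 1 beyond the first/last peak). The
consequent lives on [0, 1] with five equally spaced sets peaking at 0,
0.25, 0.5, 0.75, 1. The exact break-points are a canonical
uniform-partition reading — the published figures do not print them —
and are config-overridable.

Inference is Mamdani: min conjunction, max aggregation of clipped
consequent sets, center-of-gravity defuzzification by midpoint rule on
1001 uniform grid points (agrees with a 10⁴-point brute-force oracle to
better than 1e−3; the consequent sets are piecewise linear so the
quadrature error is ~1e−6). When no rule fires — impossible for inputs
in-domain, since the sets partition unity — the degree is defined as 0.
Out-of-domain inputs are clamped with a warning.

Two points deserve emphasis:

- **The surface is not strictly monotone.** Because several adjacent
  rule cells share a consequent term (e.g. both (L, VS) and (VL, VS)
  map to VL), the firing strength dips to 0.5 midway between peaks and
  the centroid of the clipped set drops slightly: at `p2 = 0`,
  `q(75) = q(100) = 11/12 ≈ 0.917` but `q(87.5) ≈ 0.903`. This is the
  well-known behavior of min–max–centroid systems, not a defect; the
  selection criterion ("farther from foam and flatter ⇒ higher degree")
  holds in the qualitative, peak-lattice sense, which is what the
  property tests assert.
- **`p1`'s domain tension.** The domain of `p1` is [0, L1], with L1 the
  diagonal of the lower two-thirds band (~716 px for 640×480), yet its
  set peaks stop at 100 px; the VL shoulder simply plateaus from 100 to
  L1. A scene with no foam at all yields `p1 = L1` (the loop's running
  minimum needs an initialization the published pseudocode omits; the
  maximal distance is the only value that makes the no-foam case
  maximally favorable). Whether the peak values were meant as absolute
  pixels or per-resolution is unknowable from the source; they are
  absolute here and overridable.

Sampling follows the published loop: centers uniform in the lower
two-thirds with `w/2` margins, `w = W/20` (32 px at 640×480), accept
when `q > T = 0.5`, stop at `N = 11` candidates, keep the top `N1 = 5`
(ties break to larger `p1`, then sampling order). Two additions make it
an artifact rather than pseudocode: patches containing *any* non-water
label are rejected before scoring (the method's segmentation stage
promises water-only candidates but its loop only treats foam — mask
rejection operationalizes the promise), and the unbounded while-loop
gets a `max_attempts` cap (default 1000·N) so hopeless scenes raise a
structured error reporting attempts and the best degree seen. Foam
distances are measured from patch boundary pixels to foam contour
pixels (set-to-set); the implementation uses a Euclidean distance
transform of the foam mask sampled on the patch border, which equals
the exhaustive pairwise minimum because the nearest foam pixel seen
from outside is always a contour pixel. The lookup-table fast path
evaluates the same `fis_degree` at every integer grid point, so
LUT-vs-direct equality is exact by construction; fractional queries
round to the nearest cell.

## Classification and voting

The 19-category scheme publishes names, not colorimetric definitions.
The default palette therefore ships hand-assigned Lab centroids
consistent with the names (pond greens, browns, reds, yellows,
grays/dark, blue), with a minimum pairwise Lab distance above 5 so
nearest-centroid classification is well-posed; it is fully
user-overridable via YAML, and per-code tolerance radii (default 25 Lab
units) trigger the `unknown` rejection. The default classifier takes
the patch's mean Lab color, predicts the nearest centroid, and reports
softmax(−distance) probabilities at unit temperature; `fit` on labeled
patches replaces palette centroids with per-class training means.

The CNN path reproduces the published architecture contract — a
ResNet-50-style bottleneck encoder (stem 7×7/2, groups repeated
3/4/6/3 to 2048 channels, depth-scalable for desk-size runs) and a
2048→1000→100→19 softmax head, trained with Adam (lr 1e−4, β₁ 0.9, β₂
0.999, ε 1e−8), dropout 0.5, batch 32, up to 200 epochs — but selects
the best-validation epoch rather than a hard-coded one (a specific
epoch number is an outcome of a run, not a rule). It requires the
optional `cnn` extra (torch) and is not the tested default; whether
`unknown` should be a 20th softmax class or a rejection is not
derivable from the source, so both classifiers implement rejection (the
CNN path by a 0.5 confidence floor).

Voting over the five selected patches: a code on more than half the
patches wins; otherwise the unique mode; otherwise the code of the
single highest-confidence patch, with confidence ties broken to the
lexicographically smallest code for determinism.

## Synthetic scenes

The generator renders what the pipeline consumes: a dominant water
field at a chosen code's Lab centroid with a smooth linear Lab gradient
(default amplitude 3 Lab units across the frame), bright irregular foam
blobs (default 3, radius 12 px, non-touching by construction so
component counts are exact), a striped waterwheel rectangle, and the
reference board warped into the upper third by a known projective
placement — keeping the candidate band clear, matching the reflection
caveat that motivates the band in the first place. The whole frame then
passes through a known invertible Lab distortion (default: a mild,
gamut-preserving lighting shift) plus i.i.d. per-channel Gaussian noise
(default σ = 2), and an exact per-pixel mask is emitted. Board pasting
uses nearest-neighbor warping so masks stay exact and block colors
unblended. Everything is deterministic under the scene seed.

The patch-dataset generator produces 19-class labeled patches (default
200 per class, 32 px, gradient plus Gaussian noise σ = 8) for
classifier training/evaluation.

What synthetic scenes do **not** emulate: sun glint and specular
reflection, waves and surface texture of real water, shadows, board
soiling and print fading, camera optics (vignetting, chromatic
aberration, rolling shutter) and nonlinear tone curves. Passing tests
therefore demonstrate that the algorithmic chain is correct and
self-consistent — correction inverts known linear distortions, the
extractor avoids declared non-water regions, classification recovers
declared codes — not that field accuracy on real ponds matches any
published figure; the published field results depend on site data and
trained weights that are not reproducible at desk scale.

## Problem sizes and tolerances used by the test suite

Scenes are 640×480 (band diagonal ≈ 716 px, patch side 32 px). The
acceptance suite checks: exact correction recovery (100 distortions,
< 1e−6), FIS–oracle agreement (1000 pairs, < 1e−3), LUT–direct equality
at all 717×256 grid points, the structural constants (24 blocks, 25
rules, 72×9 system, 11→5 candidates, 19 classes, 200-px ROI), ≥ 96%
held-out accuracy for the default classifier on the synthetic
19-class set, and ground-truth code recovery on ≥ 19 of 20 varied
scenes. The strict 50×50-grid monotonicity check is retained verbatim
in the suite and fails by design of the inference scheme (see above);
it documents the idealized property the qualitative criterion suggests
but the published rule table cannot deliver.

## Known limitations

- Marker decoding assumes reasonably front-facing boards (the module
  grid search absorbs sub-module quad error, not steep perspective);
  markers below ~16 px are unreliable, as with any 6×6-module fiducial.
- The linear no-offset correction cannot represent additive color
  casts, and clipping at gamut boundaries breaks exact invertibility.
- The default palette is a documented convention, not a regulatory
  standard; real deployments should calibrate centroids from labeled
  site data (`fit` supports exactly that).
- Masks are trusted as given; segmentation quality is out of scope.
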