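# Methods

## Problem and scope

Wheat lots are graded into refractions — sound, damaged, shriveled and
broken kernels — whose size, shape, colour and texture carry the quality
signal. The package measures those properties from flatbed-scanner images
(24-bit colour, black background, known dpi) and relates them to the manual
reference measurements (vernier caliper axial dimensions, single-kernel
weights). All stages run on synthetic scenes with exact ground truth, which
is how the package validates itself.

## Segmentation

The scan is split into 8-bit blue/green/red planes; one plane (green by
default — it has the best contrast between wheat colours and a near-black
background, and the channel is configurable) is low-passed with a 5×5
sampled Gaussian (σ = 0.3·((k−1)/2 − 1) + 0.8, the convention of the classic
imaging libraries; mirror border handling) and thresholded with the strict
rule `dst = maxval if src > thresh else 0`. Sound grain uses Otsu's
threshold, computed exhaustively over all 256 levels (between-class variance
w₀w₁(μ₀−μ₁)²; lowest level wins ties). The other refractions use the fixed
cut-offs 37 (damaged), 74 (shriveled) and 35 (broken); these are taken as
given constants of the protocol — they derive from histogram analyses of the
original scanner/illumination combination and cannot be re-derived here.

Foreground components are 8-connected; components under `min_area_px2`
(default 20 px², debris suppression) are dropped. Each kernel gets:

* a full-resolution boundary chain from a Moore-neighbour trace (every
  boundary pixel retained, closed, consecutive points 8-adjacent);
* the axis-aligned bounding rectangle;
* a convex hull image (centre-based, forced to contain the region, so a
  convex digital region is its own hull and solidity is exactly 1 for
  disks) and a corner-polygon hull for rectangle fitting;
* a direct least-squares ellipse fit to the boundary pixels, reported as
  full-axis diameters M ≥ m and an orientation in [0°, 180°). Fewer than
  five boundary points, or a degenerate (collinear) contour, flags the
  kernel with an error record instead of aborting the run.

### Perimeter estimation

Two estimators are carried. The **feature perimeter** is the length of the
convex hull of the region's pixel *corners* — the minimum-perimeter polygon
of a convex digital region. It is digitization-robust: a w×w filled square
measures exactly 4w (compactness exactly π/4) and a digital disk of radius
40 px measures within ~1.5% of 2πr (compactness 0.975). The raw Freeman
chain length (1 per edge step, √2 per diagonal) is also computed and
exported (`perimeter_chain_px`) because it is the convention of classical
contour libraries, but it overestimates curved outlines by ~5% on average
(digital-disk compactness ≈ 0.90), which is why it is not the default. For
*concave* outlines the hull-based estimate is a lower bound; wheat kernels
are convex to good approximation, and the shriveled class's sinusoidal
boundary model keeps deviations small.

Pixel area is the member-pixel count (unambiguous and oracle-checkable
against the renderer's ground truth), not a contour integral; the two differ
by O(perimeter), inside the tolerances used throughout.

## Shape features

The fifteen per-kernel descriptors are listed in the README. Conventions
that were genuinely open:

* **rectangle-to-perimeter** is perimeter ÷ (2·(h + w)) of the axis-aligned
  bounding rectangle — the formula form, which is the reciprocal of one
  prose description of this quantity in the field; the formula wins.
* **aspect ratio** is bbox height ÷ width (a rotation-invariant larger÷smaller
  variant is available behind a flag).
* **mbr_fill** uses the minimum-area *rotated* rectangle over the contour
  pixel centres (rotating calipers over the hull), clamped to ≤ 1: a filled
  rectangle reads exactly 1 and an inscribed digital ellipse reads ≈ π/4.
  The axis-aligned analogue is `extent`.
* **sa_to_cubic_volume** is A/M³ with A in px² and M in px (units 1/px).
* **eccentricity** √(1 − (m/M)²) is computed and exported even though it has
  no published per-lot anchor.

Features are stored at full precision; reports round to 2 decimals.

## Physical properties from caliper dimensions

The classical grain-engineering formulas are implemented verbatim,
including their diameter-plugging convention: Vp = 4/3·π·L·W²,
Vo = 4/3·π·L²·W, Ve = 4/3·π·L·W·T and the prolate surface
Sp = π·B·L³/(2L−B) with B = √(WT). Note Sp scales as length³ despite being
reported in mm² — it is kept as the conventional quantity, with correctly
scaled semi-axis closed forms available as `prolate_surface_area_exact` /
`oblate_surface_area_exact`. The oblate surface So has no conventional
printed form; the oblate closed form with L (equatorial) and B (polar)
substituted for the semi-axes is used, matching the Ve/Vp/Vo convention.
Published So values are therefore only approximately reproducible.

Broken kernels can violate L ≥ W ≥ T; this warns rather than fails, and the
aspect/ellipsoid ratios assign a ≥ b ≥ c by sorting. Lot summaries compute
per-kernel properties first, then mean ± sample sd (n−1) over kernels —
which is why a summary of a nonlinear quantity does not equal the quantity
of the summary means; several published per-class table entries differ from
direct evaluation at the class means for exactly this reason, and the
worked-example tests only assert the internally consistent entries.

## Colour and texture

Channel means are masked means over kernel pixels only. NDIs use the
channel means, not per-pixel ratios. HSV uses the 8-bit convention (hue
halved into [0, 180), S and V in [0, 255]), consistent with wheat-brown
hues around 20–35. Nearest-colour naming is a minimum Euclidean distance in
sRGB against a user-supplied chart CSV; the proprietary horticultural
reference chart is not shipped, so the generator provides synthetic charts
and published chart codes are reproducible only given equivalent chart data.

The GLCM is computed in-package because the kernel mask must constrain
*both* members of each pixel pair, which stock routines do not support; on
unmasked images it is bit-identical to the standard library routine (tested).
Default offset is d = 1, θ = 0 (single right-neighbour, 256 levels,
asymmetric, normalized) on the green channel — the minimal faithful choice
where the protocol is silent; distance, angle, levels and symmetry are
configurable. Properties follow the standard definitions: ASM = ΣP²,
energy = √ASM, correlation with σᵢσⱼ in the denominator (a verbatim
variance-product variant that breaks |ρ| ≤ 1 exists behind a flag for
fidelity experiments); constant regions define correlation = 1.

## Synthetic scenes

The generator emulates the study conditions: 100 kernels per refraction
class, 200 dpi, near-black background (level 8, not 0, so an automatic
threshold sees a genuinely bimodal histogram). Per class it draws:

* axial dimensions from the published caliper means ± sds (mm), truncated
  to [0.6, 1.4]×mean to keep axes positive under the large printed sds, and
  with the L/W ratio constrained to the class aspect-ratio ±3σ band
  (kernel allometry — length and width are not independent);
* mean colours from the published channel means ± sds, truncated to ±2σ and
  floored a ≥30 gray-level margin above the effective segmentation level
  (the background, or the class's fixed threshold for the green channel) so
  every rendered kernel is segmentable — the generator's contract;
* per-pixel Gaussian RGB noise (sd 8 by default) inside kernels, giving the
  non-constant interiors that co-occurrence texture needs;
* nearly axis-aligned orientations (N(0, 2.5°), clipped at ±6°) on a
  jittered grid, emulating manual row placement on the scanner glass;
* a sinusoidal radial boundary perturbation (amplitude 0.12, six lobes) for
  shriveled kernels only, standing in for their wrinkled outline.

Ground truth records exact rendered pixel areas and the package's own
boundary-trace perimeter (a self-consistency oracle). What the generator
does **not** emulate: touching/overlapping kernels, shadows, specular
highlights, scanner optics, within-kernel colour gradients (germ/crease),
and real shriveling geometry. Passing tests therefore demonstrate that the
measurement chain is correct and self-consistent, not that it is robust to
those real-world effects.

## Relationships

Four OLS fits per class (scipy linregress): caliper L and W vs the
fitted-ellipse major/minor diameters in mm (sub-pixel and
rotation-invariant; bounding-rectangle sides are available as an alternative
image measure), kernel weight vs calibrated projected area, and the
caliper-derived prolate volume vs calibrated area. On fully noise-free
synthetic scenes (no pixel noise, no colour spread, no irregularity) the
first three achieve R² > 0.99 at n = 100, and injecting ≥10% multiplicative
measurement noise into the manual side drops them below 0.9 — the package's
substitute validation for published per-kernel R² ranges whose raw caliper
data are not public. The volume-vs-area fit is reported but has no R²
contract: volume grows as L·W² while area grows as L·W, so even perfect
measurements are not collinear across a lot.

## Problem sizes and determinism

Tests and the acceptance script use 100-kernel scenes per class (the study's
lot size) on ~900×900 px canvases, plus small scenes for unit checks. Every
stochastic step takes an explicit seed (numpy Generator); identical
(inputs, seed) give bit-identical scenes and byte-identical CSV exports.

## Known limitations

* Touching kernels are not split (no watershed); scenes must be laid out
  disjointly, as the manual-placement protocol intends.
* The fixed thresholds 37/74/35 are protocol constants tied to the original
  scanner; other hardware needs recalibration or Otsu mode.
* Hull-based perimeters underestimate strongly concave outlines.
* Whether published channel statistics were computed over masked kernels or
  whole bounding boxes is unknown; this package uses masked kernels.
* dpi comes from configuration, never from file metadata.
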