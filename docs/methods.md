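# Methods

## Image model and normalization

All computation happens on 2-D `float64` intensity fields in [0, 1]
(row-major, origin top-left).  Integer rasters are divided by the
maximum representable value of their bit depth (255, 65535), so the
sensitivity threshold has the same meaning for 8- and 16-bit inputs.
Color images are reduced to luminance with the fixed weights
0.2989/0.5870/0.1140 (the classic ITU-R 601 weighting used by MATLAB's
`rgb2gray`).

## Preprocessing

Order is fixed: crop → invert → despeckle → smooth.  Inversion precedes
thresholding because segmentation assumes bright roots; despeckling (a
median filter, default radius 1) removes salt noise before smoothing (a
Gaussian, default σ = 1 px) so the median sees unblurred outliers.  The
defaults are the smallest effective kernels; both are configurable and
0 disables either step.  Every filter uses reflective padding — constant
padding would create an artificial dark frame that biases the adaptive
local mean near borders.

## Adaptive thresholding

A pixel is root iff `I − μ_G > T`, with `μ_G` the Gaussian-weighted mean
over an odd window and `T` an additive offset on the normalized
intensity scale (default 0.12, matching the reference operating point
for soil-root images together with area 450 px, length 46 px and
eccentricity 0.49).  The additive-offset semantics are the natural
reading of a local-mean threshold with a printed magnitude of 0.12 on
[0, 1] intensities; they make the decision exactly invariant to global
brightness shifts, which tests assert.  The default window is
`2·floor(min(H, W)/16) + 1` — large relative to root width, small
relative to the illumination gradient — with kernel σ = window/6 so the
Gaussian decays to ~3σ at the window edge.

## Component descriptors and shape filtering

Components are 8-connected so thin diagonal root segments do not
fragment.  For each component the second central moments are
accumulated in exact integer arithmetic (`n·Σr² − (Σr)²` etc.), so a
4-fold-symmetric pixel set yields eccentricity exactly 0 and a
collinear set exactly 1 — the two calibration points of the
eccentricity convention (0 = circle, 1 = line).  Axis lengths follow
the ellipse-of-same-moments convention (`4√λ`), **without** the
pixel-extent (+1/12) correction some tools add: the correction would
make a 1-px-wide line's eccentricity < 1 and break the line calibration
point.  "Length" of a component is its major axis; whether a minimum
"length" should instead mean Feret diameter or per-component skeleton
length is genuinely open, and major axis was chosen because it is
defined for every component before any skeleton exists and is monotone
in elongation.  The filter keeps a component only if it passes all
three thresholds; it is idempotent and only ever removes pixels.

## Skeleton, width, branching, length

Thinning is homotopic (Zhang's algorithm as implemented in
scikit-image), optionally preceded by binary erosion
(`erode_iterations`, default 0) to suppress boundary noise.  Junction
pixels after thinning have algorithm-dependent multiplicity, so branch
points are defined as 8-connected clusters of degree-≥3 skeleton
pixels, each cluster counted once; end points are degree-1 pixels.
Tiny compact shapes may thin to 1–2 pixels depending on tie-breaks;
tests assert the guaranteed properties (containment, thinness) rather
than one algorithm's exact pixel choice.

Local width is `2·d(p)` with `d` the exact Euclidean distance
transform, evaluated at skeleton pixels.  On a rasterized tube of
radius r the distance at the centerline is r + O(1) (typically within
~0.3 px), so widths carry a small positive bias that the phantom
recovery tests quantify (≤ 15 % for the default radius range).

Skeleton length sums 8-adjacency edges — 1 per orthogonal edge, √2 per
diagonal — dropping a diagonal when its endpoints share an orthogonal
skeleton neighbor, which prevents double counting around staircase
corners.  This estimator is exact on axis-parallel and 45° digital
lines (the two calibration cases) but, like every chain-code length
with fixed weights, overestimates obliquely sampled curves by up to
~6 % (measured ~5 % on a radius-50 digital circle); calibrated weights
(e.g. 0.948/1.340) were deliberately not used so the two exact
calibration cases stay exact.

Surface area and volume use the circular-cross-section tube model:
`Σ 2π·r_i·ℓ_i` and `Σ π·r_i²·ℓ_i`, with `ℓ_i` half the summed lengths
of the skeleton edges incident to pixel i.  The model is exactly
testable on cylinder phantoms; isolated skeleton pixels (no incident
edges) contribute nothing, so a blob that thins to a point has zero
tube volume — acceptable because the shape filter removes blobs before
trait extraction.

## Local orientation

For every skeleton pixel, an ordinary least-squares line is fitted to
the skeleton pixels inside a centered 15 × 15 px window (configurable).
The coordinate with the smaller spread is regressed on the
larger-spread one so near-vertical runs remain well-posed; ties go to
column-as-regressor.  R² and the slope F-test p-value are computed in
closed form; a perfectly collinear window (zero residual) is assigned
R² = 1, p = 0.  A pixel's angle is accepted only if the window holds
≥ 3 skeleton pixels, p < 0.05 and R² > 0.5 — junctions, where skeleton
pixels are not collinear, fail this gate and are excluded from the
orientation statistics.  The angle is reported in [0, 90]° against the
horizontal axis by default; a config switch reports it against the
vertical axis (the complement) instead, since both conventions are in
use for root angles.

## The 44-trait schema

8 scalars — root area (px count), object count, total skeleton length,
tube surface area, tube volume, branch count, end count, mean root
intensity — plus 4 distributions (horizontal position, vertical
position, local width, validated orientation) × 9 statistics (mean,
median, sd, skewness, kurtosis, min, max, 25th and 75th percentile;
percentiles use linear interpolation).  The schema reconstructs the 11
stated feature categories at the stated total of 44; individual trait
names are this package's own and are frozen in the CSV header with a
unit suffix (`_px`/`_mm`, `_px2`/`_mm2`, `_px3`/`_mm3`, `_deg`).  With a
conversion factor c (mm/px), traits scale exactly as c^k with k their
length-dimension (skewness/kurtosis, counts, angles and intensities are
dimensionless, k = 0).  An empty mask yields zero scalars and NaN
distribution statistics (the CSV sentinel for "undefined").

## Evaluation

DSC = 2·TP/(2·TP + FP + FN); two empty masks are reported as DSC = 0
with a warning (the ratio is undefined).  Histogram separability uses
256 uniform bins on [0, 1] — matching 8-bit provenance — normalized to
unit sum, and the Euclidean distance between the two class histograms;
normalized (not raw-count) histograms were chosen so the statistic does
not depend on the root/background pixel-count ratio.

## Synthetic phantoms

The generator renders roots as unions of disks along smooth,
downward-biased random-walk centerlines (unit steps; heading jitter
σ = 0.06 rad/step, relaxation toward vertical at rate 0.25), with
radius tapering linearly to 80 % of the start value.  Default scene:
384 × 384 px, 3 roots of length 150–260 px and start radius 3.5–5.5 px
(roots a handful of pixels wide, as in typical rhizobox imagery at
moderate resolution), background 0.35, roots 0.85, 15 % vertical
illumination gradient, smoothed Gaussian speckle of sd 0.08, and 8
bright elliptical "condensation" blobs of radius 3–9 px — each blob
individually below the area-450 filter threshold.  The truth mask, the
centerline length, the radius profile and the component count are
recorded exactly at generation time; all randomness flows from one
seeded generator, so identical (params, seed) reproduce scenes bit for
bit.

What the phantoms do **not** emulate: textured soil granularity with
spatial correlation beyond the speckle kernel, root hairs, overlapping
or crossing root systems, specular reflections, and intensity falloff
along the root.  Passing phantom tests therefore demonstrates
correctness of the measurement chain on known geometry, not
field-grade robustness on real soil images.

Two regime notes: (i) separability decreases monotonically with
speckle sd only while clipping at 1.0 is negligible (sd ≲ 0.1 for root
brightness 0.85); beyond that, clipping re-concentrates the root
histogram and the statistic rises again — the ordering tests operate in
the realistic sd ≤ 0.08 regime; (ii) the phantom recovery tolerances
(length 5 %, width 15 %, volume 20 % over 20 seeded scenes) reflect the
rasterization and distance-transform biases discussed above, measured
on the default radius range.

## Problem sizes

Tests and the acceptance checks use 384 × 384 phantoms, 20-seed
recovery ensembles, 10-seed separability ensembles and 100 random
32 × 32 mask pairs for the Dice oracle — sizes at which every expected
value is exactly known or independently computable, and the whole suite
runs in seconds.

## Known limitations

- Root-order topology (primary vs lateral), branching angles and
  lateral density are out of scope.
- Chain-code length bias (~5 %) on strongly oblique curves, as above.
- The trait names are a reconstruction of the stated 11 categories /
  44-trait total; other implementations may name or order them
  differently.
- Orientation statistics silently exclude invalid (junction/sparse)
  pixels; on highly branched skeletons the angle distribution describes
  the linear segments only.
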