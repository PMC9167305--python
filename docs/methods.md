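# Methods

## Scope and model

`stereovol` measures the volume of bulk material standing on a base
surface from one rectified, calibrated stereo pair (plus an optional
empty-container reference pair). It assumes: the pair is rectified
(corresponding points share a row; rectification and Zhang-style
calibration are upstream of this package and their outputs are inputs
here); disparity is non-negative with the left view as reference
(`d = u_l − u_r`); the material is seen from above, so the visible
surface is a height field over a base plane; and the container does not
move between the reference and the loaded scan.

## Matching cost

Per pixel `p` and candidate disparity `d`, three dissimilarities between
`p` and the right-image pixel at `x − d` are fused:

* **Census/Hamming** — bit strings over a window (default 9 columns × 7
  rows, the cross-based-aggregation literature's convention; 62 bits
  packed in one machine word), bit = 1 iff the neighbor is strictly
  brighter than the center, scanned row-major, replicate padding at
  borders. Depends only on intensity *orderings*, hence exactly invariant
  to any strictly increasing per-image intensity map.
* **SD** — mean over R, G, B of the squared difference; no truncation is
  applied (the robust kernel below already saturates large values).
* **Gradient** — `|∇x I_l − ∇x I_r| + |∇y I_l − ∇y I_r|` with central
  differences (replicate borders, half-step at the edge). Invariant to an
  additive bias on either image.

Census and gradient operate on ITU-R 601 luma; luma is computed as the
integer combination `(299 R + 587 G + 114 B)/1000`, which is exact in
double precision for 8-bit inputs — a plain float dot product leaves
1-ulp noise that the order-based census transform would read as contrast,
making nominally tied pixels compare inconsistently across photometric
maps.

Each component passes through `ρ(c, λ) = 1 − exp(−c/λ)` and the three
terms are summed; an individual component can saturate at most one unit
of the fused cost, so a single aberrant measure cannot dominate. Weights
λ_C = 15, λ_SD = 600, λ_G = 20 (the calibrated bench values). Every
in-range fused cost is < 3: the census term alone is bounded by
`1 − exp(−n_bits/λ_C) ≈ 0.984` away from 1. Entries whose right column
falls off the image carry the sentinel 3.0, which therefore strictly
dominates every attainable cost, and winner-takes-all breaks ties toward
the smaller disparity, so an out-of-range candidate is never selected
while an in-range one exists.

## Cost aggregation

Arms grow per pixel in the four directions while (strictly) the
max-per-channel color difference to the anchor and to the previous arm
pixel stays below τ₁ = 20, length < L₁ = 34, and additionally below
τ₂ = 6 once the arm is longer than L₂ = 17. The support region is the
union of horizontal arms over the vertical arm (or the transpose).
Aggregation averages the cost over the *joint* region
`U_d(p) = {q ∈ U(p) : q − d ∈ U′(p − d)}` with `U′` built from the right
image, normalized by the region size. Because arms are contiguous runs,
the joint region decomposes into per-row intervals bounded by elementwise
minima of the two views' arms; the implementation uses prefix sums over
those intervals and is exactly the enumerated mean (asserted against a
brute-force enumeration in the tests). Pixels with no right
correspondent (x < d) pass through unchanged.

Two passes are run by default, vertical-then-horizontal region
construction first, then the transpose — the iteration count and schedule
are not dictated by the method and are configurable. The joint region is
used in every pass.

## Disparity refinement

Order: left–right consistency labelling → filling → subpixel → 3×3
median. The right-reference map is produced by running the identical
matcher on the mirrored, swapped pair. A pixel is valid iff its disparity
agrees with the right map at its correspondent within 1 px. Invalid
pixels are *occlusions* when no integer candidate `d'` satisfies
`d' = d_right(x − d')` exactly, otherwise *mismatches*; the exact-match
discrimination follows the cross-based refinement convention — under the
tolerant ±1 rule nearly every outlier finds a "consistent" candidate and
the occlusion class would be almost empty. Occlusions are filled with the
smallest disparity among the nearest valid pixels in 8 directions
(occluded surface is almost surely background); mismatches with the
candidate of closest color.

Subpixel interpolation fits a parabola through the aggregated costs at
`d − 1, d, d + 1` and is applied only where the denominator
`C(d+1) + C(d−1) − 2C(d)` is strictly positive **and** `C(d)` does not
exceed either neighbor. The second guard is needed because filled pixels
do not sit at cost minima and the raw formula can then shift by more than
half a pixel; with both guards the shift is provably within ±0.5.

## Reconstruction and background subtraction

The pinhole relations use the left camera as origin and the baseline as
the magnitude of the dominant translation component of the calibration.
Invalid or non-positive disparities are skipped and counted. Background
subtraction keeps scene points whose nearest neighbor in the reference
cloud is farther than ε (exact coordinate equality is meaningless for
reconstructed floats). The library default is ε = 1 mm. Note that the
depth quantum of a stereo rig is `Z²/(B·f_x)` mm per pixel of disparity —
about 14 mm at the synthetic bench geometry (Z ≈ 830 mm) — so a
measurement protocol should scale ε with it; the packaged stockpile
experiment uses the depth equivalent of half a disparity step,
`ε = 0.5 Z_base²/(B f_x)`, and restricts the measured region to columns
where the full disparity range is searchable (`x ≥ d_max`), since the
left margin cannot be matched and its filled values differ unpredictably
between the loaded and the reference scan.

## Point-cloud filter and volume

Normals come from PCA over the k nearest neighbors (k = 15 by default),
flagged degenerate when the two smallest covariance eigenvalues both
vanish (collinear neighborhoods pass through unfiltered). The bilateral
step moves each point along its normal by the weighted mean of its
neighbors' normal offsets; smoothing scale σ_c defaults to the median
nearest-neighbor distance and the feature-retention scale σ_s to twice
that, adapting to sampling density; one iteration by default, normals
re-estimated per iteration. These neighborhood and scale choices are
engineering defaults — the method itself does not prescribe them.

The base plane is the least-squares plane of the background cloud when
one is given. Without a background, a least-median-of-squares search
over seeded point triples finds the dominant plane first — a plain total
least-squares fit fails whenever the raised material's height variance
exceeds the base's lateral variance, because the smallest principal axis
then lies *in* the base plane — followed by a least-squares refit on the
lowest 30% height band. Heights are oriented so the material is
positive; points below the plane are reconstruction noise, clamped to
h = 0 and counted.

Projected points are Delaunay-triangulated (exact duplicate projections
deduplicated keeping the larger height; zero-area simplices from
cocircular inputs dropped). Each triangle contributes
`projected_area × mean(vertex heights)`, algebraically identical to the
prism + two tetrahedra decomposition of the patch solid (the identity is
asserted on random triangles in the tests). Volume is therefore always
non-negative, and invariant to in-plane rigid motion of the cloud.

## Synthetic fixtures: what they emulate, and what not

Scenes are random-dot stereograms over piecewise-constant integer
disparity (base plane plus raised rectangles/disks), warped
nearest-column so the ground truth is exact; the occlusion mask comes
from forward-warp visibility (a left pixel is occluded iff a larger
disparity claims its right column). Dot textures are independent RGB
channels drawn in [10, 200), smoothed once — integer values in a
clip-free range keep gain ≥ 1 photometric maps strictly increasing per
channel after 8-bit rounding. Occluded right-image regions receive fresh
texture rather than black so outlier handling is exercised realistically.

Shape clouds sample the upward-visible surface (top faces plus the
surrounding base; vertical walls project onto curves of measure zero and
are not sampled) by stratified-uniform sampling: one point uniform in
each grid cell. A plain lattice would alias against footprint edges and
bias the skirt volume systematically with density-dependent phase; the
stratified sampler is unbiased, leaving a zero-mean skirt error whose
RMS shrinks with density. Accordingly the density-convergence check
measures the RMS volume error over a fixed ensemble of 24 sampling
realizations per density — a single realization's error is sampling noise
with no reason to be monotone.

What passing these tests does **not** show about real data: the fixtures
have fronto-parallel surfaces only (no slant within a region), exact
rectification, no lens distortion, no specularity or texture-poor
regions, and container/feed geometry far simpler than a real rearing box.
The end-to-end stockpile error (a few percent to ~13% across seeds,
tolerance 15%) is dominated by rim effects — occlusion filling erodes and
edge fattening dilates the footprint — and by convex-hull skirts between
the piles, the same mechanisms that make physical measurements of piled
material biased.

## Problem sizes and numerical choices

Validation scenes are 160×120 with ≤ 25 disparity levels and fixture
clouds up to ~10⁵ points; these sizes put every stage's error far above
float noise while keeping the full suite and the acceptance script in the
minutes range. Tolerances: oracle equivalence of the cost volume at
1e-12 (identical arithmetic, modulo summation order), aggregation at 1e-9
(prefix-sum vs naive summation order), geometric roundtrips at 1e-6 mm,
and the patch-volume identity at 1e-9 relative. Ties in WTA go to the
smaller disparity; all arm-rule comparisons are strict, as are both
subpixel guards.

## Known limitations

* Scanline-optimization parameters sometimes present in parameter tables
  (π₁, π₂, τ_SO, τ_S, τ_H) are accepted in configs but inert — no
  scanline pass is implemented.
* Delaunay triangulation covers the convex hull of the projections, so
  concave footprints and separated piles are over-covered; an optional
  circumradius-based triangle filter is deliberately absent to keep the
  plain method.
* Gaps inside piled material are invisible to any surface method; the
  measured volume is the envelope volume.
* The LR-consistency check cannot flag pixels where both views agree on a
  wrong disparity (a ~1 px zone at occlusion-band edges).
* PFM, PLY (ascii) and XYZ are the only cloud/disparity formats; 16-bit
  PNG export requires an explicit scale.
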