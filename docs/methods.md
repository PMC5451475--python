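# Methods

This note documents the measurement model, the defaults and why they were
chosen, the synthetic-data model used for validation, and the numerical
choices that a user of the package should know about.

## Scan geometry and units

All physical quantities derive from a `ScanGeometry` (width/height in mm,
pixel counts). The reference scan pattern is 3 mm × 3 mm sampled by
320 × 320 A-scans (9.375 µm/px, 8.789 × 10⁻⁵ mm²/px). Pixels are indexed
row-major from the top-left; a pixel's physical extent is the half-open
square `[x·s, (x+1)·s)`, so every area is a pixel count times the exact
pixel area — no resampling or interpolation is applied anywhere in the
measurement chain. Intensities are normalized to [0, 1] by the declared
bit depth (255 or 65535), never by per-image min/max, so thresholding
behaves identically across a batch. No gamma correction is applied; export
gamma of vendor software is unknown and treated as part of the image.

A quality gate excludes scans whose metadata score is below 40 (the
conventional cutoff for this device class); scans without a score pass
with a warning, since automated gating cannot replace manual artifact
grading (motion, blur, decentration), which is out of scope.

## Denoising

Non-local means with patch radius 2 (5 × 5 patches), search radius 7
(15 × 15 window), and filter strength h = 0.08 of the dynamic range.
Each output pixel is `Σ w_j x_j / Σ w_j` over the search window with
`w_j = exp(−d²_j/h²)`, `d²_j` the mean squared patch difference; weights
sum to one, so the output is confined to the convex hull of the input
intensities. Borders are mirror-reflected (zero padding would bias border
statistics dark). The defaults suppress speckle-scale noise at 320 × 320
without erasing single-pixel-scale capillaries; on the synthetic scenes
below they reduce the background noise SD by roughly an order of
magnitude. All three parameters are configurable.

## Binarization

Phansalkar adaptive local thresholding: vessel iff
`I > t = μ·(1 + p·e^(−q·μ) + k·(σ/r − 1))`, with μ, σ computed over a
square window of radius 15 px (≈ 0.28 mm) with mirrored borders. The
constants are the original published ones (k = 0.25, r = 0.5, p = 2,
q = 10), with σ normalized on the [0, 1] intensity scale (r = 0.5 = half
dynamic range). The exponential term raises the threshold where the
window is dark, which is what makes the method usable on dark-background
angiograms. With p = q = k = 0 the rule degenerates to local-mean
thresholding, which the tests exploit as a sanity anchor. Binarization is
deterministic: identical input and parameters give a byte-identical mask.

A known property of this operator (verified on the synthetic scenes): on
soft, partial-volume vessel edges it cuts well below half-amplitude, so
vessel masks are dilated by a fraction of a pixel relative to the
geometric half-coverage boundary. This inflates vessel area slightly and
is the main driver of the small positive bias in measured VD and of
circularity under-recovery in noisy scenes; see "Validation" below.

## FAZ segmentation and shape

Region growing returns the 4-connected component of background pixels
containing the seed; 4-connectivity prevents leakage diagonally through
single-pixel capillary junctions. The seed defaults to the scan centre
(scans are fovea-centred; decentred scans are a quality-control exclusion)
and may be set explicitly. A seed landing on a vessel is moved to the
nearest background pixel with a warning. A breach in the enclosing
capillary ring makes the region leak into the surrounding background;
this is documented behavior, not an error — the operator measures exactly
the connected avascular region.

The boundary is traced as a closed 8-connected chain (Moore neighbourhood
following). Two chain-length estimators are available:

* `chain` — axial step = 1 px, diagonal = √2 px. Simple, but it
  overestimates the length of smooth digitized contours by ≈ 5 % (the
  classic chain-code bias), which alone would depress the circularity of
  a perfect digital circle to ≈ 0.90.
* `corner_corrected` (default) — the Vossepoel–Smeulders estimator
  `0.980·n_axial + 1.406·n_diag − 0.091·n_corner`, unbiased to < 1 % on
  smooth contours. This is what makes the circularity of a digitized
  circle ≈ 1.00.

Circularity is the isoperimetric quotient `4πA/P²`, i.e. the ratio of the
region's area to that of the circle with equal perimeter. The
equal-perimeter circle is evaluated in closed form rather than by
re-rasterizing a circle into the pixel grid: the closed form is the limit
of the rasterization procedure and removes grid-orientation artifacts.
Rasterization can still push the quotient marginally above 1 for
near-circular regions; values above 1 are clipped to 1.0 and logged,
honoring the index's defined range of 0–1.

## ETDRS grid and vessel density

The grid is the 1 mm central disk and 1–3 mm parafoveal annulus; a pixel
belongs to a zone iff its centre lies inside the circle. The grid centres
on the FAZ centroid (fovea proxy; configurable to the image centre), and
the outer circle must fit in the scan to within one pixel — a
fovea-centred 3 mm grid on a 3 mm scan is exactly tangent.

Non-perfused regions are 8-connected components of background pixels
strictly larger than 0.02 mm² (227.6 px at the reference scale, so 228 px
is the smallest qualifying count). Components are clipped to the zone
before the area test: a component straddling the zone boundary counts
only its in-zone pixels. VD is then
`100 × (zone area − Σ qualifying component areas) / zone area`; dark
areas at or below the cutoff count as perfused. The FAZ itself is not
excluded from any zone's denominator (or numerator), so the central and
total VD of a healthy macula sit below 100 % by roughly the FAZ fraction
of the zone.

## Skeleton, fractal dimension, caliber

The mask is thinned to 1-px 8-connected centerlines by Guo–Hall iterative
thinning, which preserves topology (component count) and leaves no 2 × 2
blocks; Zhang–Suen is available behind a flag but can leave 2 × 2 blocks.
Skeleton length sums each undirected 8-neighbour link once (axial links
at the pixel size, diagonal at the Euclidean diagonal), avoiding double
counting.

Fractal dimension is computed on the skeleton by default (`fd_source`
switches to the raw mask): box counting over dyadic box sizes
s = 2, 4, 8, … up to a quarter of the image side, grid anchored at the
origin (no offset averaging), FD = least-squares slope of log N(s) versus
log(1/s) over all computed scales. At least three scales are required
(image side ≥ 32 px). Calibration: a straight line scores 1.00 and a
filled plane 2.00, both within 0.05, with fit R² > 0.95.

VDI = vessel mask area / skeleton length (mm): the mean vessel caliber.
For a straight bar of width w it recovers w·pixel_size to within a pixel
(thinning shortens the bar ends slightly).

## Reliability statistics

* **ICC** — ICC(A,1): two-way, absolute-agreement, single measurement,
  `(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`, the standard
  choice for test–retest of a single device where systematic session
  shifts should count against agreement. The 95 % CI uses the
  McGraw–Wong F-distribution bounds. ICC(C,1) (consistency) is available
  behind a flag. The implementation is cross-checked in the tests against
  an independent ANOVA hand computation and against `pingouin`.
* **CR** — 1.96 × SD of the within-subject differences of two sessions
  (the Bland–Altman convention); 95 % of repeat differences are expected
  below CR. CI by chi-square bounds on the difference variance. The
  alternative 2.77 × within-subject-SD convention (usable for k > 2) is
  available via a flag.
* **Bland–Altman** — mean difference and mean ± 1.96 SD limits of
  agreement, with an optional plot.
* **ICC precision** — the large-sample variance
  `2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1))` (Bonett 2002) propagated through the
  Fisher-type transformation `Z = ½·ln((1+(k−1)ρ)/(1−ρ))`; the CI is
  formed on the Z scale and back-transformed, so widths respect the
  [0, 1) boundary. Under this relation a 30-subject, 2-rater design
  resolves an ICC of 0.86 with a 95 % CI width of 0.20; `icc_for_width`
  inverts the relation by bracketed root finding. All intervals are
  two-sided 95 %.

## Synthetic scenes and what they validate

A scene is built from one integer seed driving one generator (no global
random state):

* **FAZ** — boundary `r(θ) = R·(1 + Σ_{m=2..6} a_m cos(mθ + φ_m))` with
  amplitudes scaled by `faz_irregularity` (0 = perfect circle) and capped
  so the radius stays positive. Truth area, perimeter and circularity are
  computed by quadrature (4096 θ samples) on this continuous curve —
  independent of the raster pipeline, hence a legitimate oracle. Default
  radius 0.35 mm (a typical adult FAZ of ≈ 0.38 mm²).
* **Vessels** — a terminal capillary ring whose inner edge sits on the
  FAZ boundary; branching random-walk trees (root caliber ≈ 3 px,
  tapering, branch probability per step = `branch_density`) rooted just
  outside the ring and growing outward, with a one-pixel clearance margin
  so that soft stroke edges never intrude on the avascular zone; and an anastomotic background capillary mesh
  drawn as curved edges of a jittered lattice (spacing 8 px, caliber
  ≈ 2 px, matching the PSF-broadened apparent caliber of capillaries in
  OCT-A). The mesh matters: real superficial-plexus angiograms are
  closed-loop capillary beds whose enclosed avascular pockets are far
  smaller than the 0.02 mm² rule, so qualifying non-perfusion arises only
  from the FAZ and from genuine dropout. Without closed loops the
  background forms sprawling near-threshold dark components and VD
  becomes an unstable quantity — un-physiological and hypersensitive to
  single-pixel edge placement.
* **Dropout** — disk patches (centre in mm, radius in mm) where vessels
  are erased; these are the controlled source of non-perfusion.
* **Noise** — `clean·(1 + speckle·u) + N(0, σ)` clipped to [0, 1], with
  u a standard normal field; defaults σ = 0.05, speckle = 0.15. Strokes
  are rendered with a one-pixel anti-aliased edge (distance-transform
  soft disks), so binarization is exercised on realistic soft edges.

`generate_repeatability_set` emulates the two-scan test–retest design:
each subject gets its own structural parameters (FAZ radius/shape,
branching density) and two images differing only in the noise draw. When
all structural spreads are set to zero, every subject shares one anatomy,
giving a pure-noise design whose ICC should collapse toward zero.

Validated recovery at the reference scale (320 px, defaults): total VD
within 5 percentage points of continuous-model truth across branching
density × dropout conditions (observed errors are typically < 1 pp once
the capillary bed is closed-loop); FAZ area within 10 % (typically ≈ 1 %);
circularity within 0.1 of truth for irregularity up to 0.3. The VD and
circularity errors are dominated by the binarization edge bias described
above. Test problem sizes (scene counts, subject counts) are kept modest
since recovery errors are driven by systematic, not sampling, effects.

What the scenes do *not* emulate: physically realistic OCT speckle and
decorrelation statistics, projection artifacts from overlying vasculature,
motion artifacts, cystoid spaces (which this method cannot distinguish
from non-perfusion), or vessel-caliber distributions of real plexuses.
Passing recovery tests therefore demonstrates internal consistency of the
measurement chain on controlled geometry, not clinical accuracy.

## Degenerate inputs and error policy

Every contract violation raises a distinct named error: oversized filter
windows, geometry/dimension mismatches, color images, all-vessel masks
(no FAZ seed), empty regions, zero perimeter, zero skeleton length, too
few box scales, unbalanced or zero-variance repeated-measures tables,
infeasible scene parameters. An all-background mask grows to the whole
image ("unbounded FAZ") with a warning rather than an error; a region
touching the scan border is measured along the clipped contour with a
warning. Scans failing the quality gate yield a record with
`qc_pass=False` and missing metrics unless processing is forced.

## Known limitations

* Perimeter (and hence circularity) depends on the boundary-length
  estimator; the corner-corrected default is accurate on smooth shapes
  but both estimators are biased on structures a few pixels across.
* The binarization edge bias slightly inflates vessel area/VD and
  deflates circularity under noise; it is a property of the thresholding
  operator, not a bug, and is quantified by the synthetic recovery tests.
* FAZ leakage through a genuinely broken terminal ring is by design;
  users measuring pathologic FAZs should inspect the saved region mask.
* No magnification correction for axial length is applied; areas are in
  nominal scan millimetres.
* Only the superficial plexus image class is modeled; deep-plexus
  projection-artifact handling is out of scope.
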