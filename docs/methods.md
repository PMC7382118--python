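# Methods

This note records the scientific and numerical choices behind
`carrotshape`: what is modelled, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Segmentation

A carrot on a bright background is dark in the blue channel (orange
reflects red/green, absorbs blue), so segmentation thresholds the blue
plane and takes the *dark* side as foreground. The threshold is Otsu's
method by default — parameter-free and well suited to the strongly
bimodal histograms this rig geometry produces — with a fixed-integer
override and an `invert` flag for dark-background rigs. A constant plane
has no two-class structure and raises a degenerate-image error rather
than guessing.

Cleaning follows the conventional connectivity pairing: 8-connectivity
for foreground components, 4-connectivity for the background flood that
defines holes (the dual pairing that avoids topological paradoxes).
Order of operations: fill holes, clear border-touching components holding
less than half of the foreground (frame artifacts), drop components below
`min_area_fraction` (default 0.05) of the largest, keep the single
largest component, fill again. The chain is idempotent, hole filling
never removes foreground and cleaning never adds any. All modules share
one coordinate convention: row-major, origin top-left, 0-based,
pixel-center coordinates.

## Shape descriptors

Area is the foreground pixel count. The perimeter is the polygon length
of the marching-squares 0.5-level contour after Douglas–Peucker
simplification at 1 px tolerance: the raw staircase contour overstates
smooth boundaries by ~6%, which would bias the isoperimetric ratios;
after simplification a rasterised disc measures within ~1% of 2πr and a
square within ~1% of 4s, while a plain boundary-pixel count can be wrong
by up to ~27%.

Length *a* and width *b* are the pixel-span extents along and across the
principal (second-moment) axis — the natural frame for an elongated root
photographed at arbitrary orientation — so an axis-aligned 10×4
rectangle reports exactly 10 and 4. The moment-ellipse major/minor axes
and eccentricity are reported separately (via `skimage.regionprops`);
extent is A/(a·b). Roundness 4πA/p² and compactness p²/A satisfy
Ro·Co ≡ 4π algebraically, which the featuriser asserts for every sample
as a self-check. For near-isotropic shapes the principal axis is
ill-defined; extents are swapped if needed so a ≥ b always.

## Partition features

The silhouette's pixel centers are projected onto the principal frame;
the axial span is cut into 7 equal intervals, each pixel assigned to
exactly one slice (the slice areas tile the silhouette). Per slice, the
centroid and the maximum perpendicular pixel span over unit axial
columns are measured. Slices are renumbered thick-end-first (by
comparing the width mass of the two halves) so feature indices do not
depend on which way the carrot was laid down; a 180° rotation leaves
every feature unchanged.

Two interpretation choices in the nonhomogeneity definitions:

- The centroid difference c_i − c₄ is taken on the coordinate
  *perpendicular* to the principal axis only. The along-axis coordinates
  of slice centroids differ by ~length/7 by construction and carry no
  shape information; only the perpendicular offset measures bending.
- Absolute values are used for both Fc_i and Fb_i, so offsets on
  opposite sides of the midline cannot cancel in the totals.

The totals are normalised by b_m = max_i b_i ("the biggest width") —
defined on slice widths rather than the global width so the definition
stays internally consistent with the partition (the two coincide for
convex silhouettes). Both totals are scale-free: the same shape rendered
at 1× and 2× resolution agrees within a few percent.

An empty slice (a broken root imaged in two pieces) reports width 0,
borrows the nearest non-empty slice's centroid for Fc, and sets a
`broken` flag in the feature row instead of failing.

The root count N is the larger 8-connected component count of the two
terminal slices, and the maximum is taken over both ends so orientation
does not matter. Forks that separate before the final seventh of the
length are counted there just the same.

## Discriminant analysis

Classes are modelled as Gaussians; prediction maximises
log π_c − ½log|Σ_c| − ½(x−μ_c)ᵀΣ_c⁻¹(x−μ_c). LDA uses the pooled
within-class covariance (denominator n − k), QDA per-class covariances
(denominator n_c − 1). Numerical choices:

- **Standardisation** (per-feature center/scale from the training data)
  before fitting. The descriptors span several orders of magnitude
  (extent ~0.5 vs perimeter ~10³) and z-scoring stabilises the
  covariance inversion; at ridge 0 the decision rule is mathematically
  unchanged by any per-feature affine map.
- **Ridge** ε added to covariance diagonals, default 10⁻⁶ × mean
  diagonal variance. Near-constant features — the root count is exactly
  1 for every regular sample — make class covariances singular; the
  default ridge regularises them without materially moving the rule.
  With ε = 0 a singular covariance raises an error naming the implicated
  features (from the smallest eigenvector's large components).
- **Ties** at equal scores go to the lower class label,
  deterministically.
- Cholesky factorisation for determinants and Mahalanobis terms, with an
  explicit eigenvalue check so exact singularity is reported as such
  rather than surfacing as a numerical accident.

Evaluation reports the confusion matrix and CCR (percent, 2 decimals).
Cross-validation (leave-one-out or seeded stratified k-fold) refits
everything — including standardisation — inside each training fold, and
pools the single out-of-fold prediction per sample. The headline fixture
rates are resubstitution (fit and evaluate on the full set), with the
cross-validated rates reported alongside and labelled, since either
protocol is defensible for a 135-sample study and the two are easy to
confuse.

## Feature selection

Greedy sequential forward selection, scored by stratified 5-fold
cross-validated QDA CCR: the simplest wrapper consistent with selecting
features "by cross-validation based on QDA". Stopping is strict
improvement (δ = 0); ties between candidates resolve by column order, so
a fixed seed and table give a byte-reproducible result. A lone candidate
must beat the majority-class baseline to be selected at all. The
univariate screen (Welch's unequal-variance t-test per feature, class
means/SDs, CV% = 100·SD/mean with population SDs) is provided for
Table-style reporting; a feature constant in both classes is flagged
`undefined` rather than tested.

## The synthetic generator

What it emulates: a single root as a tapered band of width
w(t) = base_width·((1−t)(1−0.12) + 0.12)^taper around a quadratic-arc
midline with peak offset `curvature`·length; forked roots (2–3 thinner
branches diverging past a branch point); broken roots (flat truncation);
arbitrary orientation (rendered analytically — every pixel center is
inverse-rotated into the carrot frame, so rotation adds no resampling
artifacts); smooth per-sample width lumpiness and midline wiggle (random
low-order cosine series) emulating natural root-to-root variation; and
an RGB rendering with dark-blue-channel carrot (≈50) on a bright
background (≈230) plus Gaussian pixel noise.

Default conditions (in `src/carrotshape/data/generator_defaults.yaml`):
lengths 360–460 px, base widths 70–100 px, taper 0.85–1.25, orientation
±8°, noise σ = 6; regular curvature ≤ 0.02 with a single unbroken root;
irregular samples draw one morphology — curved (curvature 0.08–0.25,
weight 0.45), forked (weight 0.30), broken (cut at 50–75% of length,
weight 0.15) or curved+forked (0.10). The standard fixture is 56 regular
+ 79 irregular at seed 2020. Problem sizes throughout (fixture of 135,
500-shape root-count sweeps, 100 selection replicates) were chosen so
the full suite and the acceptance run each complete in well under a
minute on a laptop core.

What it does **not** emulate — and hence what passing tests do not show
about real data: photographic texture, shadows, specular highlights and
uneven illumination; soil, foliage or multiple objects; genuine damage
morphologies beyond clean breaks; and the true morphometric
distribution of field-grown carrots, for which no reference measurements
are available. Classification rates on this fixture demonstrate that the
pipeline recovers the class structure its descriptors are designed to
capture, not field performance.

## Known limitations

- Single-object scenes only; no colour calibration or illumination
  correction.
- The 7-slice scheme assumes the principal axis is a sensible spine;
  hook-shaped roots that fold back on themselves would break the
  monotone axial parametrisation (the generator's curvature range stays
  well clear of this regime).
- Part counts other than 7 are accepted as a parameter but only the
  7-slice configuration is exercised against ground truth.
- Roundness/compactness on silhouettes smaller than ~8 px across are
  dominated by discretisation error; the descriptors are intended for
  objects hundreds of pixels long.
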