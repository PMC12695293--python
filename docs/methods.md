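# Methods

This note documents the measurement model, the statistical procedures, the
synthetic phantom that serves as the package's test oracle, and the numerical
conventions behind them. It is the place where genuinely open design choices
are recorded.

## Disc Height Index

For a spinal level (one of L1/2 … L5/S1) with disc height `h_IVD` and the
heights `h_cr`, `h_ca` of the cranial and caudal vertebral bodies, the Disc
Height Index is the dimensionless ratio

    DHI = 2 · h_IVD / (h_cr + h_ca).

The ratio normalises disc height by local vertebral size, so it is invariant
under isotropic rescaling of the image and comparable across subjects and
scanners. Typical adult lumbar values fall around 0.25–0.40.

### Height measurement

Field usage rarely pins down an operational definition of "height" for a
segmented structure on a sagittal slice. This package uses the following,
chosen to be robust to lordotic curvature, endplate curvature and mild
wedging, and to admit an exact analytic oracle:

1. **Level axis.** For each disc level the measurement direction is the unit
   vector from the cranial vertebral body's centroid to the caudal one's,
   computed in millimetre coordinates (`row·row_spacing`, `col·col_spacing`).
   A local axis per level, rather than the image vertical, makes the
   measurement equivariant under global image rotation and correct in curved
   spines. All three structures of a level (disc and both vertebral bodies)
   are measured along the *same* axis, so each DHI record is internally
   consistent; a vertebral body shared by two levels may receive slightly
   different heights at each, and each record stores the heights it actually
   used.
2. **Mean trimmed chord.** Member-pixel centres are rotated into the frame
   (u along the axis, v across it) and binned across v with bin width equal
   to the smaller spacing component (avoiding aliasing under anisotropic
   spacing). The chord length in a bin is `count · pixel_area / bin_width`.
   Bins whose centre lies outside the central 80% of the occupied v-extent
   are discarded; the height is the mean of the remaining chords. The 10%
   margins suppress endplate curvature, corner rounding and small boundary
   islands. Connected components are deliberately not enforced: annotation
   masks may contain small islands, and the trim handles outliers.

The statistic is exact for axis-aligned rectangles whose side is a multiple
of the row spacing, which is what makes the phantom an analytic oracle. A
bin index is computed with an epsilon-tolerant floor (`+1e-9` on the
fractional index) so that coordinates landing a rounding error below a bin
edge do not split into phantom bins.

Degenerate inputs: a missing structure makes the level's record incomplete
(flagged, never raised, DHI = NaN); coincident vertebral-body centroids or a
zero summed vertebral-body height raise a degenerate-geometry error.

## Agreement statistics

* **Dice / IoU** are computed per structure from pixel counts; a structure
  empty in both masks has an undefined score and is excluded from
  aggregation. One mask pair is aggregated as mean ± SE across its 11
  structures; multiple subjects as mean across subject-level means. The
  identity DSC = 2·IoU/(1 + IoU) holds as exact rational arithmetic on the
  counts and is property-tested.
* **Bland-Altman** on paired DHI series uses differences oriented
  first-minus-second (A − B), sample SD with denominator n − 1, and limits
  of agreement at bias ± 1.96·SD. The paired t-test is two-sided Student t
  with n − 1 degrees of freedom. When the differences have zero spread, the
  t statistic is undefined; the result carries the bias with a degenerate
  flag rather than an arbitrary number.
* **R²** is the squared Pearson correlation — symmetric in the two raters,
  unlike a regression R² with one series as the response. The 95% CI is the
  2.5th/97.5th percentile of R² over resamples of pairs with replacement
  (default 1000); the percentile method was chosen over BCa as the simplest
  standard construction. Resamples in which either series is constant are
  skipped and logged. Per-level CIs reuse the same integer seed per level,
  so restricting the input to one level reproduces the grouped result
  exactly. A Monte-Carlo study (200 simulations, n = 150 bivariate-normal
  pairs, true ρ² = 0.9) puts the empirical coverage of the 95% CI at 93–96%.

## Preprocessing operators

* **Percentile clipping** clamps intensities to the 0.5th/99.5th percentile
  bounds (configurable), with percentiles defined by linear interpolation
  between order statistics at rank `p/100·(n−1)`. The operator is monotone.
  It is exactly idempotent whenever the clip ranks fall inside tie runs of
  the histogram — the usual case for discrete-intensity medical images. On
  tie-free data the recomputed percentile of the clipped image drifts by at
  most one inter-order-statistic gap at the clip rank, so re-application can
  move boundary pixels by that gap; tests assert exact idempotence on tied
  histograms and bound the drift otherwise.
* **Median filtering** uses a square window (default side 11) with
  edge-sample-repeating reflection at the borders (the `reflect` mode of
  scipy.ndimage, equivalent to numpy's `symmetric` padding), which avoids
  dark frame artefacts. The brute-force oracle in the tests enumerates every
  window explicitly under the same convention.
* **Geometric scaling** resamples to `round(dim · factor)` pixels per axis
  and divides the spacing by the factor, so physical extent is preserved to
  within one pixel pitch. Grayscale images are interpolated bilinearly;
  label masks use nearest-neighbour so the emitted label set is always a
  subset of the input's. DHI, being a physical-space ratio, is unchanged by
  scaling to within rasterization error.
* **Augmentation sampling** composes clip → blend toward the
  median-filtered image with a uniformly drawn weight → random scale from
  the configured range, all driven by one seeded generator. The random blend
  weight is this package's concrete mechanism for the "slight random
  intensity variation" role the filter stage plays in augmentation
  pipelines; a kernel of 1 and a degenerate scale range reduce the
  composition to the clip alone.

## Synthetic spine phantom

The phantom emulates a labeled T2 mid-sagittal lumbar mask: six vertebral
bodies (rounded rectangles) and five discs (rectangles) stacked
cranio-caudally, each structure boundary rotating the running direction by
half the inter-level angle so a full level accumulates the whole angle and
the stack curves like a lordotic spine. Defaults: 512×512 grid at 0.5 mm
isotropic spacing, vertebral heights 27–30 mm, depths 32–35 mm, disc heights
8–10.5 mm, disc depth 0.9× the mean adjacent vertebral depth — representative
adult lumbar dimensions at clinical sagittal resolution. The random sampler
draws vertebral heights from U(24, 32) mm, depths from U(30, 38) mm, disc
heights from U(6, 12) mm and the per-level tilt from U(0°, 10°).

Ground truth (per-structure heights and per-level DHI) is computed from the
generating parameters, never from the raster, keeping the oracle independent
of the measurement code. Two rasterization details matter:

* membership along the spine axis is half-open, so an axis-aligned height
  that is a whole multiple of the row spacing covers exactly that many pixel
  rows — zero-tilt phantoms are measured *exactly*;
* vertebral corner rounding uses radius `min(0.15·height, 0.09·depth)`. The
  depth cap keeps the rounding strictly inside the 10% cross-axis trim
  margin of the chord statistic, so rounding never biases the measured
  height of an axis-aligned body. (Without the cap, corner arcs would leak
  into the averaged chords and shave a few tenths of a millimetre.)

Across 50 sampled phantoms (0.5 mm spacing, tilts up to 10° per level) the
maximum |measured − analytic| DHI error is ≤ 0.02; the residual comes from
the half-angle mismatch between a structure's own axis and the
centroid-to-centroid level axis (a cos θ/2 factor, ≈ 0.4% at 10°) plus
rasterization noise.

**Rater perturbation.** A simulated second annotator displaces each
structure's boundary by thresholding its signed Euclidean distance field
(pixel units, negative inside) at `bias + noise`, where the noise field is
white Gaussian noise smoothed with a σ = 3 px Gaussian and rescaled to the
requested displacement SD. A structure may claim its own original pixels or
background, never a sibling's pixels, so labels cannot swap between
structures; contested background goes to the structure whose displaced field
is deepest. Zero bias and zero jitter is the identity by construction. One
consequence worth knowing: at structure-structure interfaces (disc-endplate
boundaries) the constraint makes jitter one-sided — interfaces can erode but
not advance — so even "unbiased" jitter induces a small systematic DHI
offset in the perturbed rater, which is visible (and correctly exposed) in
the Bland-Altman output of the simulated two-rater study.

**What the phantom does not emulate:** MRI texture and intensity
inhomogeneity, pathology (herniation, severe degeneration, transitional
vertebrae), posterior elements, partial-volume boundaries, or the
inter-subject correlation structure of real cohorts. Passing phantom tests
therefore demonstrates correctness of the geometry and statistics under
known ground truth, not clinical validity of the height definition on real
anatomies.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to be
representative while staying lightweight: 50 sampled phantoms for DHI
recovery; 20 phantom subjects (360×300 px at 1 mm) for the simulated
two-rater study (100 DHI pairs); 200 simulations × 1000 bootstrap resamples
for CI coverage; 30 subjects for the batch-pipeline checks. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* The chord-mean height is one defensible operationalization of "height";
  alternatives (mid-line distance, anterior/middle/posterior averages) would
  give slightly different absolute values. It is validated against analytic
  phantoms, not against a clinical reference standard.
* The mid-sagittal slice of a 3D volume is taken as `floor(n/2)` along the
  sagittal axis — a convention, not an anatomical determination.
* PNG masks carry no physical spacing; without an override the package
  assumes 1 mm isotropic (warned). DHI is unaffected under isotropy, but
  absolute heights then are pixel counts.
* Overlap aggregation (mean ± SE across structures, then across subjects)
  is one of several defensible conventions; per-structure values are always
  reported so users can re-aggregate.
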