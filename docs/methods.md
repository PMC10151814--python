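# Methods

This note documents the models, conventions and numerical choices behind
`cmrqc`, and what the synthetic phantoms do and do not establish about
real data.

## Data model and conventions

Contours are simple polygons in 0-based subpixel pixel coordinates
(x = column, y = row); the outer ring is counter-clockwise (positive
shoelace area), holes are clockwise. Physical quantities are obtained by
scaling coordinates with the anisotropic pixel spacing *(row, col)* in
mm/pixel before any area or distance computation. Slice index 0 is the most
apical acquired slice and indices increase toward the base; the file format
records the acquisition order and the reader normalises base-to-apex stacks
on load. The myocardium is always the derived region *epi − endo*, never
stored; a slice's endocardial contour must lie inside the epicardial one up
to a tolerance of 1% of the endocardial area, beyond which loading fails
with a containment error naming the slice.

One polygon per structure per slice is stored. Fragmented raster
predictions are resolved at import time by largest-polygon postprocessing
(see I/O below), matching how CNN outputs are post-processed before
contour-level evaluation.

## Volumetry

Volumes use disc summation: Σ over segmented slices of region area (mm²)
× slice spacing (thickness + gap, mm) / 1000. No partial-disc interpolation
is applied at the base or apex; users comparing absolute volumes against
tools that interpolate a partial basal disc should expect small systematic
differences. Myocardial mass is myocardial volume at ED × density
(default 1.05 g/ml, configurable). A slice with an epicardial but no
endocardial contour contributes its full epicardial area to the myocardium
(the cavity is taken to vanish apically); each such slice is logged.

## Geometric metrics

Dice is computed by polygon clipping in mm coordinates,
100·2|A∩B|/(|A|+|B|). Operands are ordered canonically before clipping so
the result is bit-exactly symmetric. The Hausdorff distance is evaluated on
boundary point sets resampled so consecutive points are at most 0.25 px
apart (configurable); the reported value is then within two resampling
steps of the true contour Hausdorff distance. For the myocardium the point
set contains both the epicardial and endocardial rings — the region's
boundary is both rings; an alternative convention (epicardial ring only)
would miss pure endocardial displacement, and the choice is recorded in the
run metadata.

Comparison-level conventions: a slice segmented by neither reader scores a
Dice of 100%, a slice segmented by only one reader scores 0%; these values
are applied in `compare_slice`, not inside the pure `dice()` operation,
which keeps the geometric primitive total and separately testable. The
Hausdorff distance is defined only when both readers segmented. Of the two
Dice averages, the all-slices mean includes the convention values and is
reported without an sd (the zeros distort the distribution); the
segmented-by-both mean is reported with a sample sd.

## Slice-position stratification

Positions are assigned per structure and per phase (the basal extent can
differ between ED and ES). With E the expert's segmented slice set and R
the reader's: the basal block is max(E) plus every slice above it in R;
the apical block is min(E) plus every slice below it in R; slices strictly
between the anchors are midventricular — including interior slices the
reader skipped, which count as false negatives there. Reader slices above
the basal anchor are basal even if separated from it by an unsegmented gap.
If the expert segmented a single slice it is classified basal. If the
expert segmented nothing, positions are undefined: all slices are
unassigned, and reader false positives are reported in a separate
unassigned row rather than silently dropped. Stratified tables pool ED and
ES, report one row per (entity × basal/mid/apical) plus per-position rows
pooled over entities; per-slice absolute volume differences are averaged
over slices segmented by at least one reader (neither-slices carry no
volumetric information).

## Statistics

Paired two-sided t-tests use n−1 degrees of freedom on reader−expert
differences; a zero-variance nonzero-mean difference vector is flagged
degenerate (t = ±∞, p = 0) rather than erroring. Pearson correlations are
pooled across parameters as tanh(mean(atanh r)); correlations of exactly ±1
are excluded from pooling (infinite z). No multiple-testing correction is
applied across the seven parameters — raw per-parameter p-values at
α = 0.05 are reported. ICC(3,1) is the two-way mixed-effects consistency
single-rater coefficient (MS_R − MS_E)/(MS_R + (k−1)·MS_E) with the
F-distribution 95% CI; a residual mean square below 10⁻¹² of the
between-subject mean square is treated as zero so per-rater additive
offsets yield ICC = 1 exactly. Equivalence uses the t-based 95% CI of the
mean difference (a normal-based CI would be marginally narrower; the
t-based choice is recorded in run metadata) and declares equivalence when
the CI lies inside the configured tolerance interval, inclusive at the
boundaries. Tolerance intervals are runtime configuration: they derive from
intraobserver variability studies and are site-specific, so the package
ships no defaults.

## I/O

The contour-stack format is a single JSON document (schema version "1",
`docs/contour_stack_schema.md`). Floats serialise with Python's shortest
round-trip representation, keys and records in fixed sort order, so writes
are byte-deterministic and read(write(stack)) is vertex-bit-exact. The
`phase_grids` header preserves acquired-but-unsegmented slices so decision
errors beyond the expert's extremes remain representable after a round
trip. Mask import vectorises each label's binary image by marching squares
at iso-level 0.5 (subpixel), reconstructs the epicardial contour as the
boundary of the union of the blood-pool and myocardium labels, and keeps
the largest polygon per structure; rasterisation labels a pixel by polygon
coverage of its centre (boundary inclusive), with myocardium = inside epi
and outside endo.

## Synthetic phantoms

The generator reproduces the acquisition geometry of a routine short-axis
cine protocol: 7 mm slices with no gap, 256×256 images at 1.4 mm in-plane
resolution, ED and ES annotated. Defaults give a plausible adult heart
(LVEDV ≈ 98 ml, LVEF ≈ 60%, LVM ≈ 91 g, RVEF ≈ 50%); the cohort sampler
varies base radius (21–28 mm), wall thickness (6–10 mm), slice count
(8–12) and contraction between cases. The LV is a stack of circles with an
ellipsoid-like apex-to-base taper; the RV is the difference of an offset
disk and the epicardial disk (a crescent; its ground-truth area is the
shoelace area of the generated polygon itself, so truth is exact with
respect to the geometry actually emitted). ES contours are ED contours
contracted about their centroid — EF = 100·(1 − c²) for linear contraction
c — with the ES epicardial radius chosen to conserve myocardial ring area
(wall thickening). One empty margin slice beyond apex and base keeps
false-positive decision errors representable. Per-case RNG substreams are
derived by stable hashing of (seed, case id), so cohorts are reproducible
and order-independent.

Error models emulate characteristic CNN failure modes: radial over-/under-
segmentation (vertices moved along centroid rays by δ mm; the volumetric
effect is book-kept exactly from the polygon areas), contour translation,
basal/apical decision errors (drop the anchor slice and/or add a shrunken
copy beyond it with configured probabilities), fragmentation (replace the
contour by a similar shape of a fraction of the area), and smooth boundary
jitter (low-frequency radial Fourier noise with total sd in mm — iid
per-vertex noise would self-intersect at realistic vertex densities). A
perturbation that breaks endo-in-epi nesting on a slice drops the LV pair
from that slice and records a decision error, mirroring how an implausible
prediction would present. What the phantoms do **not** model: realistic
image intensities, papillary/trabecular anatomy, through-plane motion,
valve-plane geometry, or correlated inter-slice errors. Passing phantom
tests therefore validates the measurement pipeline (metrics, volumetry,
stratification, statistics) — not any claim about how a particular network
behaves on clinical images.

## Problem sizes and numerics

Default cohort analyses use 29 cases × 8–12 slices × 2 phases at 256
boundary vertices per contour; a 256-gon underestimates the circle area by
~8·10⁻⁵ relative, far below the 1% recovery tolerance. The Hausdorff
resampling default of 0.25 px bounds the discretisation error at ~0.35 mm
for 1.4 mm pixels and ~0.25 mm at unit spacing. Statistical calibration
checks use 2,000 null simulations at n = 20. Degenerate inputs (empty
polygons, constant rating grids, empty buckets) return explicit undefined
markers (`None`/NaN) rather than silent zeros.
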