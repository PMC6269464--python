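# Methods

This note documents the models, conventions and numerical choices behind
`angioarch`, and what its synthetic benchmarks do and do not demonstrate.

## Data model

All analysis operates on `BinaryStack`: a 3D boolean grid with an
isotropic voxel size (default 0.54 µm). Coordinates are `(z, y, x)`,
0-based; z is the TIFF page index. On read, any nonzero pixel is signal —
inputs are assumed already binarized and isotropically resampled by
upstream preprocessing, which this package deliberately does not
replicate. Anisotropic input is rejected rather than resampled.

## Caliber classification

The caliber proxy of a vessel voxel is its **minimal projected
cross-section**: the smallest of the areas of the 2D connected signal
components containing the voxel in the XY, XZ and YZ slices through it.
In-slice components use 8-connectivity by default (diagonal-touching
lumen pixels read as one section; 4-connectivity is available). The area
is component voxel count × voxel face area.

*Known bias:* sections are measured in the three Cartesian planes, not
perpendicular to the local vessel axis, so a straight tube oblique to the
grid reads up to √3 times its true cross-section (worst case along the
body diagonal). Since class boundaries are octaves (each bound is half the
previous), a tube whose transverse section sits in the lower half of a
class cannot leave the class through obliquity alone; tubes in the upper
half can drift one class up. Curvature and vessel junctions can push
sections further up, including past the top boundary.

Classes are upper-inclusive: class k holds areas a with
`boundary[k-1] ≥ a > boundary[k]`, with an implicit final bound of 0
(exclusive of background). Defaults are the printed sequence 74.6, 37.3,
18.6, 9.33, 4.67, 2.33, 1.17 µm², i.e. 0.54² × {256, 128, 64, 32, 16, 8, 4}
rounded to three significant figures (one value, 18.66 → 18.6, is the
truncated rounding; all agree within 0.5%). `CaliberClassScheme.from_voxel_size`
builds the exact-product variant for other voxel sizes. Areas above the
top boundary get an over-caliber sentinel label and are excluded from all
downstream volume and dispersion computations.

Hole filling precedes classification: per 2D slice, in each of the three
slicing orientations, background not connected to the slice border becomes
signal, and the three results are unioned — so a tube's open lumen fills
from the orientation that cuts it transversely. A 26-connected speck
filter of configurable minimum component size is available but off by
default, since the upstream segmentation pipeline is expected to have
filtered noise already.

## Dispersion index (halo, nHv95%)

Raw cycles: iterated binary dilation of the signal, clipped at the grid
border, until the signal fills at least 95% of the grid volume (the full
grid is the denominator). One cycle is one elementary dilation; the
default scheme alternates the 26-neighborhood (cubic) and 6-neighborhood
(octahedral) 3×3×3 structuring elements, starting with the cube. The
Minkowski limit of this alternation is the sum of a cube and an
octahedron — a rhombicuboctahedron-like solid whose radial anisotropy
(max/min extent over the 26 lattice symmetry directions) is ≤ 1.25 after
≥ 10 cycles, versus √3 for pure cubic growth; this makes cycle counts a
reasonable surrogate for Euclidean distance. The element pattern is
configurable (`FACE6`, `EDGE18`, `FULL26` in any repeating order) and is
recorded in all outputs, since absolute cycle counts depend on it.

Termination is the first cycle meeting-or-exceeding the target; the
achieved fill is reported, and no fractional-cycle interpolation is done
(the index is defined in integer cycles).

**Normalization.** Samples with more initial volume trivially need fewer
cycles. nHv95% therefore subtracts, per sample, the number of initial
cycles needed to reach the *greatest initial V% observed in the analysis
batch*. The batch spans all cumulation levels of all samples of all
groups entering one comparison — computed once, passed explicitly, never
recomputed per group — so nHv axes are comparable across groups. The
reference resolution is recorded in the run manifest. With no reference,
the raw count is returned unchanged.

## V/D fingerprints

Cumulated tree k is the union of caliber classes 1..k (over-caliber
excluded); 7 trees per sample. Per tree, (V%, nHv95%) gives one point of
the V/D curve, ordered by level. Volumes are non-decreasing and raw cycle
counts non-increasing in the level by construction (set union can only
grow the dilation seed).

If a class is empty, its tree equals the previous one; the point is kept
(so curves always have 7 levels) but flagged, and flagged duplicates are
excluded from line fits. An empty level-1 tree (no large vessels at all)
is an error: the curve's left end is undefined.

Fits are ordinary least squares of nHv on V% with R² = 1 − SS_res/SS_tot
and a t-based 95% CI on the slope. Group curves take pointwise medians
with 25–75% IQRs (linear interpolation between order statistics — the
percentile method is stated in output metadata). Two group-level slope
summaries are reported, clearly labelled, because they answer different
questions: the fitted slope of the median curve, and the median of
per-sample fitted slopes. Group-level projected lengths are medians of
per-sample lengths, not the median curve's own span. Group comparison uses
a two-tailed unpaired Student's t-test for two groups, or one-way ANOVA
followed by Bonferroni-adjusted pairwise t-tests (adjusted p = min(1, raw
p × number of pairs)) for more; significance stars at 0.05 / 0.01 / 0.001,
with raw and adjusted p-values and box-plot summary statistics emitted.

## Synthetic phantoms

`generate_phantom` rasterizes populations of tubes: each vessel is a
polyline centerline (unit steps, angular jitter up to a configurable
tortuosity per step, walked in both directions from its seed until it
exits the grid or exhausts a length cap) thickened to the population
radius via a Euclidean distance transform. Populations are drawn from
largest to smallest radius. Three placement models for independently
seeded vessels:

* `uniform` — uniform random positions;
* `stratified` — jittered cells of a shuffled k³ grid partition;
* `hypoxic` — jittered farthest-point sampling on the distance map to
  existing signal, emulating hypoxia-driven angiogenic sprouting (new
  vessels grow where tissue is least perfused).

A per-population hierarchical fraction seeds the rest of the vessels on
existing larger vessels ("sprouting"); the seed point is pushed about one
voxel clear of the parent wall so parent and daughter stay adjacent
without their projected sections merging into one component. The split
between hierarchical and infiltrating vessels is deterministic
(round(h × count)), which keeps per-class composition stable across seeds.
Identical spec + seed gives bit-identical stacks; the ground-truth report
lists per-population voxel counts and the intended class of a straight
tube of that radius.

**Packaged cohort.** `default_cohort()` yields 8 phantom specs (two
stacks per "tumor", four tumors; per-tumor count scaling 0.85–1.15×) on
128³ grids at 0.54 µm, with one population per caliber class. Radii are
set just above each class's lower area boundary so obliquity keeps
straight vessels in class; counts rise and lengths shrink toward small
calibers so each level adds a decreasing V% increment while cumulative
infiltrating counts grow enough to keep the dispersion decline roughly
linear. These constants are fixture calibration: they define a cohort
whose V/D curves are near-linear (per-sample R² ≥ 0.95) with volumes in
the realistic 0.5–2.5 V% range. 128³ is the chosen problem size for the
packaged benchmarks; `PhantomSpec` itself defaults to 256³.

**Depletion and treatment transforms.** `deplete_random` removes exactly
round(fraction × N) uniformly chosen signal voxels (exact-count sampling
was chosen over per-voxel Bernoulli for testability). `deplete_classes`
emulates a vascular-targeted treatment; by default it prunes whole
vessels — 26-connected components of the signal whose dominant caliber
label is a targeted class — until about the requested fraction of the
class volume is gone (overshoot capped at 1.3× the target so one giant
connected tree cannot silently wipe out a class). Whole-vessel pruning
matters: scattering holes into a large vessel merely fragments it into
smaller-caliber pieces and moves the fingerprint the wrong way, and
deleting only the class-labeled voxels leaves the vessel's smaller-reading
end caps behind as debris. A uniform voxel-deletion mode is retained.

## What the synthetic benchmarks show — and what they don't

The phantom cohort demonstrates that the implementation reproduces the
method's qualitative behavior end to end: near-linear V/D curves with
negative slopes; slope stability (≤ 15% relative change, typically ≤ 6%)
under 10% random signal depletion; and, under a simulated anti-angiogenic
prune of the largest and smallest calibers, the expected signature —
up-/left-shifted left end, steeper median slope, shorter median X length,
with near-linearity preserved.

Phantoms are not tissue: vessels are constant-radius tubes without
tapering, bifurcation statistics, flow-consistent hierarchy or imaging
artifacts, and grids are ~70× smaller than real confocal stacks. Absolute
slopes and cycle counts therefore do not transfer to real data (they also
depend on the structuring-element sequence); only the method's invariants,
contracts and qualitative contrasts are validated here. The
dispersion-index granularity is one integer cycle, which on small grids is
the dominant noise source in fit quality.

## Numerical and degenerate-input conventions

* Class binning is exact floating-point comparison against the boundary
  list; areas are exact multiples of the voxel face area.
* `cycles_to_fill` on an empty signal with a positive target is a domain
  error; a stack already at target needs 0 cycles.
* A normalization reference below a sample's own initial V% is a
  configuration error (the batch maximum was mis-computed); equality
  within floating-point tolerance gives offset 0.
* Fits require ≥ 2 points with distinct V%; all-identical abscissae are a
  domain error. With exactly 2 points the slope CI is undefined (NaN).
* Group comparison requires ≥ 2 groups of ≥ 2 samples; two identical
  constant groups report p = 1 rather than the 0/0 t statistic.
* Vessel radii below half a voxel may rasterize empty and produce a
  warning in the ground-truth report; hierarchical seeding without any
  parent falls back to independent placement and is counted in the report.
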