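# angioarch

Quantification of 3D tumor micro-angioarchitecture from binary vessel
stacks: caliber classes, progressively reconstituted vascular trees, a
morphological dispersion index, and near-linear **V/D fingerprints** that
summarize a whole microvascular network with a handful of comparable
parameters.

## Who this is for

Researchers analyzing 3D microscopy of microvascular networks — e.g.
functional vessels in tumor xenografts labeled in vivo, segmented to
binary isotropic z-stacks — who want compact, statistically comparable
descriptors of vascular amount, caliber composition and spatial dispersion
across treatment groups, without skeletonizing vessels into branch/node
graphs.

## The method

Input is a binary, isotropic voxel grid (default 0.54 µm voxels; nonzero =
vessel signal), read from multipage TIFF.

1. **Caliber classification.** Each vessel voxel is assigned the area of
   the smallest 2D connected vessel section through it among the three
   orthogonal slicing planes (its *minimal projected cross-section*, a
   caliber proxy). Areas are binned into 7 descending classes bounded by
   74.6, 37.3, 18.6, 9.33, 4.67, 2.33, 1.17 and 0 µm² (successive halvings
   of 0.54² × 256 µm²). Sections above 74.6 µm² are *over-caliber* and
   excluded. Hollow lumina are filled first.
2. **Cumulated trees.** Tree *k* is the union of classes 1..k — from
   "largest vessels only" (k = 1) to the whole sub-75 µm² network (k = 7).
3. **Volume and dispersion per tree.** V% = 100 × signal voxels / total
   voxels. The dispersion index **nHv95%** counts morphological expansion
   cycles (alternating 26- and 6-neighborhood dilations, a
   rhombicuboctahedral growth scheme) until the signal fills ≥ 95% of the
   volume, minus the cycles needed to reach the batch's greatest initial
   volume (cross-sample normalization). Lower nHv95% = more evenly
   dispersed vessels.
4. **Fingerprint.** The 7 (V%, nHv95%) points form a near-linear curve.
   Its descriptors: slope ℝ (cycles per V%-point, negative; shallow =
   dense microvessels adjacent to larger ones, steep = fewer, distant
   small vessels), left/right endpoints (large vessels / whole tree), and
   the X/Y projected lengths (microvascular volume below 37 µm² and the
   dispersion it contributes). Groups are summarized by medians with
   25–75% IQRs and compared by two-tailed unpaired t-tests (2 groups) or
   one-way ANOVA with Bonferroni-adjusted pairwise tests (> 2).

A seeded phantom generator (tubes with per-class radii, hierarchical
"sprouting" adjacent to parent vessels, hypoxia-guided infiltration and
exact-count random depletion) makes every stage testable without any
imaging data.

## Worked example

```python
import angioarch as aa

cohort = aa.default_cohort(n_samples=3, shape=(96, 96, 96))
samples = [(sid, aa.generate_phantom(spec)[0]) for sid, spec in cohort]
result = aa.analyze_samples({"ctrl": samples})
fit = result.groups["ctrl"].median_fit_params
print(fit.slope, fit.r_squared, fit.left_end, fit.right_end)
```

Running `python examples/04_vd_fingerprint.py` (this computation plus
per-sample detail) prints:

```
t1_s1: [(1.87, 44), (3.04, 28), (3.97, 22), (4.49, 18), (4.83, 15), (5.04, 14), (5.17, 13)]
   slope ℝ = -9.0 cycles per V%-point, R² = 0.976
...
median curve: slope -8.3 (95% CI -9.1 to -7.5), R² 0.993
  left end  (large vessels only): V% 1.87, nHv 39.0
  right end (whole tree):         V% 5.00, nHv 12.0
  X length 3.07 (microvascular volume below 37 µm²), Y length 27.0
```

Each bracketed pair is one cumulation level: V% grows as smaller calibers
are added while nHv95% falls — the near-linear inverse relation (R² ≥ 0.96
per sample) whose slope, endpoints and projections are the network's
fingerprint. The other scripts in `examples/` demonstrate phantom
generation, caliber classification, the dispersion index, and a simulated
anti-angiogenic treatment contrast.

## Command line

A thin CLI wraps the same pipeline:

```sh
angioarch simulate --out-dir phantoms/              # default 8-sample cohort
angioarch classify phantoms/t1_s1.tif --out-dir labels/
angioarch fingerprint --group ctrl=a.tif,b.tif --group drug=c.tif,d.tif \
    --out-dir results/ --plot
angioarch deplete in.tif out.tif --fraction 0.10 --seed 1
```

`fingerprint` writes a V/D CSV (sample, level, V%, raw/offset/nHv cycles),
a fingerprints JSON (per-sample and per-group parameters plus statistics),
an optional median V/D plot, and a manifest echoing every resolved setting
for reproducibility.

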