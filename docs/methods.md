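# Methods

## Problem and scope

Dual-reporter in utero electroporation labels intermingled control (green)
and experimental (red) neurons in the same cortical section, so migration can
be compared within a slice instead of between section-matched brains.
`migratron` implements the measurement side of that design: automated
detection of fluorescent somata in two-channel confocal z-stacks, signed
distance from each cell to user-drawn curved boundaries (top of the cortical
plate, ventricular surface), curvature-conforming binning, and the paired
statistics that exploit the within-slice control. Wet-lab steps, microscope
stitching, interactive ROI drawing, and morphological phenotyping (neurites,
branching) are out of scope; ROIs are read from ImageJ `.roi`/`.zip` files or
a CSV dialect.

## Detection pipeline

Each channel is processed independently and deterministically:

1. **Unsharp mask** per z-slice: `sharpened = I + w·(I − G_r(I))`, clipped to
   the 16-bit range. Defaults `r = 10 px`, `w = 0.6` — typical values for
   somata of 10–20 px diameter.
2. **Gaussian blur** per z-slice, `σ = 2 px`.
3. **8-bit conversion** by linear min–max rescale of the whole stack. This
   makes the automatic threshold invariant to constant intensity offsets.
4. **Threshold.** `auto` mode applies Otsu to the 8-bit histogram (the
   deterministic default of common ImageJ workflows). `fixed` mode bypasses
   the 8-bit image entirely and compares the *original 16-bit* values against
   a fixed gray value — the convention used for leakiness testing, where an
   artificially low threshold of 1000 of 65 535 catches even very dim cells.
5. **Binary erosion**, iterated, with an in-plane 3×3 cross (1 iteration by
   default). Kernels for steps 1, 2 and 5 are 2D because optical sections are
   ~1 μm apart against ~0.3–0.5 μm pixels; 3D kernels would be strongly
   anisotropic.
6. **Watershed split** of touching objects, driven by the 3D Euclidean
   distance transform with anisotropic sampling (`z_step/pixel_size`). The
   distance transform is lightly smoothed (σ = 1.5 px in-plane, 0.5 slices
   in z) before seeding, otherwise pixel noise on the mask outline spawns
   spurious maxima inside single somata and over-segments them. Maxima closer
   than `min_peak_separation_px` (default 8) are merged before seeding, and
   any connected region left without a seed receives its distance-transform
   argmax, so no object can be swallowed by a brighter neighbour. The split
   is realized by removing the voxel shell where two watershed labels meet
   (a 2-voxel gap), because downstream labeling uses 26-connectivity, which
   would bridge a 1-voxel line diagonally. A single 3D watershed is used
   rather than slice-wise 2D splits: slice-wise split lines drift between
   sections and 26-connectivity can then bridge around them, fusing
   neighbouring cells.

**3D object counting.** Foreground voxels are labeled with 26-connectivity,
so in-plane regions that overlap or touch diagonally in adjacent sections are
one cell. On top of that, components whose per-slice XY centroids in
*adjacent* z-slices fall within `merge_radius_px` (default 4) are merged even
without voxel contact — a cell split by noise in one section is still counted
once. Per label, the center of mass is computed with original-image intensity
weights (pixel centers at `index + 0.5`), brightness is the mean original
16-bit intensity over member voxels (mean rather than integrated intensity:
scale-free with respect to cell size), and labels outside
`[min_voxels, max_voxels]` are discarded and logged (`min_voxels = 30`;
`max_voxels` defaults to 50× `min_voxels` to drop fused clumps, and its
triggering is logged prominently).

**Double positives.** A green and a red cell whose XY centers lie within
`match_radius_um` (default 5 μm, about half a soma) and whose brightnesses
both exceed `brightness_threshold` (default 1000 of 65 535) form a
double-positive pair; matching is greedy nearest-first with each cell in at
most one pair, both members are flagged, excluded from all statistics, and
written to an audit CSV with pair distances. The matching rule is a
documented reconstruction — the leakiness protocol defines the phenomenon
and the threshold, not the pairing algorithm.

## Geometry

Distances are computed in 2D (x, y) from the 3D center of mass: ROIs are
drawn on the section plane and ~12 μm of imaging depth is negligible against
hundreds of μm of migration. The distance to a polyline is the minimum
Euclidean distance over all segments (closest point may be a segment interior
or a vertex). The sign is determined by the side of the locally closest
segment, with vertex ties resolved by the angle bisector of the two incident
segments; the positive side is the side containing the *other* boundary's
centroid. This reproduces the convention that a cell beyond the
cortical-plate top has a negative distance to it, without assuming a global
"up" axis, so it generalizes to arbitrarily curved sections.

The default migration metric is the distance to the cortical-plate top (the
distance remaining to travel; it isolates radial migration better than
distance from the ventricle, which mixes in tangential motion); the distance
to the ventricle is always reported alongside.

**Relative position and bins.** For a cell with non-negative distances to
both boundaries, `rel_pos = d_cp / (d_cp + d_vent)` ∈ [0, 1]; a cell beyond a
boundary clamps to that boundary (0 or 1) and carries an out-of-band flag.
Bins are equal half-open intervals of relative position (`[i/n, (i+1)/n)`,
last bin closed at 1, 10 bins by default); because relative position is
measured between the two curved boundaries, the bins conform to the actual
curvature of the section instead of being straight rectangles. Flagged cells
land in the boundary bin on their side and keep the flag. Interpreting the
"closest-ROI" banding as relative-distance banding is a reconstruction; the
exact construction of the curved bins is not specified by the protocol this
reimplements.

## Statistics

The unit of analysis is the per-slice per-color mean of the migration
distance (one dot per slice and color, matching the presentation of the
original design), not a cell-level mixed model. `paired_color_anova` fits a
two-way ANOVA with factors color and slice on those means (statsmodels OLS +
type-II ANOVA); only the color-effect p-value is surfaced, since variation
between slices is a nuisance absorbed by the slice factor. When the
within-slice color difference is exactly zero everywhere the color sum of
squares is zero and the report short-circuits to F = 0, p = 1. Slices missing
a color are dropped from paired analyses and logged. The signed effect is the
mean over slices of (green mean − red mean), in μm.

`absolute_variance_internal` summarizes the per-slice |green − red| mean
difference as mean ± SEM (plus the signed color-bias mean ± SEM).
`absolute_variance_matched` aligns two brains' serial sections at a landmark
slice index (e.g. the first slice with an uninterrupted corpus callosum),
pools all fluorescent cells across colors within each slice (a
cell-count-weighted mean), compares matched positions, and drops and logs
unmatched slices.

`two_sample_test` applies the normality-gated rule: each sample is screened
with a Kolmogorov–Smirnov test against a normal distribution with the
sample's fitted mean and SD (α = 0.05; the classical KS form — the source
protocol names the KS normality test without specifying a Lilliefors-type
correction); if both samples pass, a two-tailed t-test is used, otherwise a
two-tailed two-sample KS test. The report records which branch fired. No
multiple-testing correction is applied — comparisons are single and planned —
and the CLI does not loop tests silently.

## Synthetic data generator

The generator renders what the pipeline is meant to measure, with known
ground truth:

- **Boundaries** are concentric arcs (cortical curvature proxy) discretized
  at 2 μm vertex spacing; defaults put the cortical-plate top at radius
  1560 μm and the ventricle at 1060 μm, a 500 μm deep band — a realistic
  cortical depth for the late-embryonic mouse sections this emulates, and
  deep enough that truncating migration distances to the band perturbs their
  means only marginally.
- **Cells** (300 per channel by default) are placed at angles uniform over
  the imaged span and at depths from the cortical-plate top drawn from a
  truncated normal (defaults: mean 150 μm, SD 60 μm per channel, truncated
  10 μm inside both boundaries). Placement uses the inward normal of the
  closest boundary point, so the true distance equals the sampled depth;
  stored ground-truth distances are nevertheless recomputed against the
  *realized* polylines, making ground truth and geometry code consistent to
  machine precision. A minimum inter-cell spacing of 1.5× the soma diameter
  (12 μm by default, enforced across channels) keeps detection benchmarks
  well-posed; setting `min_spacing_factor = 0` gives a crowding mode.
- **Rendering**: each soma is a 3D Gaussian blob (radius 4 ± 0.5 μm,
  σ_z such that it spans ~3–5 sections of a 12-section, 1 μm-step stack) with
  peak intensity 8000 ± 2000 on the 16-bit scale over a background of 200,
  with Poisson photon noise plus Gaussian read noise (SD 30) — putting both
  the Otsu threshold and the fixed 1000 threshold in sensible regimes.
  Field of view is 800 × 624 μm at 0.5 μm/px.
- **Double positives** (1% of cells by default) are single cells rendered at
  the same XY position in both channels and marked in the ground truth.
- **Slice-level offsets** (SD 50 μm by default) shift both colors' migration
  means together, emulating the developmental gradients along the
  rostro-caudal and medio-lateral axes that make section matching
  unreliable. An injected color effect Δ shifts only the red mean
  (Δ > 0 = migration deficit: red cells sit farther from the cortical-plate
  top).

What the generator does **not** emulate: neurites and differentiated
morphology, DAPI nuclear texture, vasculature, optical PSFs beyond Gaussian
blobs, bleed-through (cross-channel signal is modeled only as discrete
double-positive cells), tiling/stitching artifacts, and depth-dependent
attenuation. Passing tests therefore demonstrate the correctness of the
measurement machinery on blob-like somata at realistic SNR, not robustness to
every tissue artifact.

## Simulation sizes and numerical choices

- Experiment-level statistical properties (type-I calibration, recovery of an
  injected 60 μm deficit, internal-control vs section-matching variability)
  are computed on the generator's distance-level fast path
  (`generate_experiment(render=False)`): the statistics consume per-cell
  distances, and rendering hundreds of full stacks would only re-test the
  pixel pipeline, which is benchmarked separately against rendered ground
  truth. Sizes used: 200 null experiments of 6 slices for calibration, 50
  experiments for effect recovery, 50 brain pairs of 8 slices for the
  variance comparison; detection is benchmarked on one full 600-cell rendered
  scene and the double-positive rule on a 200-cells-per-channel scene with a
  5% double-positive fraction.
- The recovered effect under Δ = 60 μm is biased slightly low (~56 μm): with
  slice offsets of SD 50 μm, low-offset slices push the green distribution
  against the near boundary and band truncation compresses the realized
  difference. This is a property of the bounded geometry (cells cannot
  overshoot the boundaries by construction), not of the estimator.
- Determinism: every stochastic step is driven by a single integer seed
  through `numpy.random.default_rng`; identical seed + parameters give
  bit-identical stacks, ground truth and CSV outputs. Detected cell ids are
  assigned by sorting centers of mass by (z, y, x).
- Degenerate inputs: constant or all-zero stacks yield an empty mask with a
  warning; an empty mask yields zero labels; a slice with no cells of one
  color carries a missing marker and is excluded from paired tests; bins with
  no cells report 0%.

## Known limitations

- The centroid-merge radius (4 px) and the double-positive match radius
  (5 μm) are heuristics chosen for ~8 μm somata; densely packed or much
  smaller cells need retuning (all parameters sit in the run config and are
  logged per run).
- Brightness quantification ignores background subtraction; with the default
  background of a few hundred gray values against thresholds of 1000+ this is
  negligible, but heavily autofluorescent tissue would bias it.
- ROIs are treated as 2D curves applied to all z of a stack (they are drawn
  on the projection); strongly tilted sections would need per-slice ROIs.
- The two-way ANOVA on per-slice means discards within-slice cell-count
  differences; slices with very few cells of one color get equal weight.
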