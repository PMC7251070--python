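# migratron

Automated quantification of neuronal migration in dual-color confocal
z-stacks, with curvature-conforming binning and paired internal-control
statistics.

## The problem

In utero electroporation experiments that compare a control and an
experimental condition across different brains depend on *section matching* —
aligning serial sections between animals at an anatomical landmark — and the
developmental gradients of the embryonic cortex make that comparison noisy.
A dual-reporter design removes the problem at the source: a limiting dose of
Cre pseudorandomly switches transfected cells from a green reporter to a red
reporter plus the experimental manipulation, so control (green) and
experimental (red) neurons are intermingled **in the same section**, and
every slice carries its own control.

`migratron` is the measurement machinery for that design. For each
two-channel z-stack it:

1. detects fluorescent somata per channel (unsharp mask → Gaussian blur →
   8-bit conversion → automatic Otsu or fixed 16-bit threshold → erosion →
   3D distance-transform watershed → 3D object counting that merges the same
   cell across optical sections);
2. flags and excludes **double-positive** cells (bright in both channels
   within a match radius — ambiguous control/experimental identity);
3. measures each cell's signed distance `d_cp` to the user-drawn
   cortical-plate-top curve and `d_vent` to the ventricle curve (negative
   beyond a boundary), its relative position
   `rel = d_cp / (d_cp + d_vent)`, and its bin among *n* equal
   relative-position bands that follow the curvature of the section;
4. summarizes each slice per color and runs the paired statistics: a two-way
   ANOVA (color × slice) on per-slice mean distances whose color-effect
   p-value tests whether red cells migrate differently from green ones, the
   per-slice |green − red| "internal-control" variability (mean ± SEM), and
   the section-matching analogue between two brains aligned at a landmark
   slice.

A synthetic-data module generates two-channel sections with known ground
truth (curved boundaries, truncated-normal migration distances, Gaussian-blob
somata, Poisson + read noise, optional co-located double positives, and
slice-level offsets emulating developmental gradients), so every stage is
testable without microscope data.

## Worked example

```python
from migratron import SceneParams, analyze_slice, generate_slice, match_to_ground_truth

params = SceneParams(seed=11)          # 300 cells/channel between curved boundaries
green, red, rois, truth = generate_slice(params)
result, dp_pairs = analyze_slice("s0", green, red, rois)

for channel in ("green", "red"):
    detected = [c for c in result.cells if c.channel == channel and not c.double_positive]
    rep = match_to_ground_truth(detected, truth.per_channel(channel, include_double_positive=False),
                                match_radius_um=4.0, pixel_size_um=params.pixel_size_um)
    print(channel, f"recall {rep['recall']:.3f} precision {rep['precision']:.3f} "
                   f"rmse {rep['rmse_px']:.2f} px")
```

prints

```
green recall 1.000 precision 1.000 rmse 0.05 px
red recall 0.997 precision 1.000 rmse 0.05 px
```

i.e. essentially every rendered soma is recovered, none is hallucinated, and
centers of mass are accurate to a twentieth of a pixel. The
`examples/` directory has one short narrative script per capability
(detection, signed distances and bins, paired internal-control statistics,
double-positive exclusion), each printing the numbers it computes and what
they mean.

## Command line

```bash
migratron simulate --config sim.yaml --seed 7 --n-slices 6 --output-dir data/
migratron analyze  --config run.yaml          # cells.csv, bins.csv, slice_summary.csv,
                                              # stats_report.csv, QC overlay PNGs
migratron compare  brainA_out/ brainB_out/    # internal-control vs section-matching
                                              # absolute variance (mean ± SEM)
```

Every run writes its fully resolved configuration next to its outputs and
logs each decision (threshold chosen, size-filtered objects, excluded double
positives, slices dropped from pairing), so results are reproducible from
config + inputs. See `docs/methods.md` for the model, parameter defaults and
their rationale, and known limitations.

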