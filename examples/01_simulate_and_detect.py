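"""Render a synthetic two-channel section and recover its cells.

Generates a small curved cortical band with 40 green + 40 red cells, runs
the full detection pipeline (unsharp mask -> blur -> Otsu -> erode ->
watershed -> 3D object counting), and compares detections to ground truth.
"""
import numpy as np

from migratron import SceneParams, analyze_slice, generate_slice, match_to_ground_truth

params = SceneParams(
    image_shape=(12, 640, 800),
    arc_center_um=(200.0, 800.0),
    cp_radius_um=760.0,
    vent_radius_um=560.0,
    migration_mean_um={"green": 80.0, "red": 80.0},
    migration_sd_um={"green": 40.0, "red": 40.0},
    n_cells=40,
    double_positive_fraction=0.0,
    slice_offset_sd_um=0.0,
    seed=42,
)
green, red, rois, truth = generate_slice(params)
result, dp_pairs = analyze_slice("demo", green, red, rois)

print(f"true cells per channel: {params.n_cells}")
for channel in ("green", "red"):
    detected = [c for c in result.cells if c.channel == channel]
    report = match_to_ground_truth(
        detected, truth.per_channel(channel),
        match_radius_um=params.soma_radius_um_mean, pixel_size_um=params.pixel_size_um,
    )
    print(
        f"{channel}: detected {report['n_detected']}, recall {report['recall']:.2%}, "
        f"precision {report['precision']:.2%}, centroid RMSE {report['rmse_px']:.2f} px"
    )
# recall/precision near 1 and sub-pixel RMSE mean the watershed + 3D object
# counter recovered essentially every rendered soma at its true position.
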