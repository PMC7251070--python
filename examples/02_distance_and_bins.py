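"""Signed distances to curved boundaries and curvature-conforming bins.

Builds two curved ROIs (cortical-plate top and ventricle), places a few
cells by hand — one beyond the cortical-plate top — and shows the signed
distance convention, relative position and bin assignment.
"""
import numpy as np

from migratron import RoiPolyline, assign_bins, relative_position, signed_distance

theta = np.linspace(-0.4, 0.4, 60)
cp_top = RoiPolyline("cp_top", np.column_stack([500 * np.sin(theta), 600 - 500 * np.cos(theta)]))
ventricle = RoiPolyline("ventricle", np.column_stack([300 * np.sin(theta), 600 - 300 * np.cos(theta)]))

cells = {
    "deep cell": (0.0, 280.0),
    "mid-band cell": (40.0, 210.0),
    "arrived cell": (-30.0, 110.0),
    "overshoot cell": (0.0, 85.0),  # above the cortical-plate top
}
print(f"{'cell':>15} {'dist_cp (um)':>13} {'dist_vent (um)':>15} {'rel_pos':>8} {'bin':>4}")
for name, xy in cells.items():
    d_cp = signed_distance(xy, cp_top, ventricle.centroid)
    d_vent = signed_distance(xy, ventricle, cp_top.centroid)
    rel, flagged = relative_position(d_cp, d_vent)
    b = assign_bins([rel], 10, [flagged])[0]
    marker = " (beyond cp_top)" if flagged else ""
    print(f"{name:>15} {d_cp:13.1f} {d_vent:15.1f} {rel:8.3f} {b:4d}{marker}")
# dist_cp is the distance left to migrate: 0 at the cortical-plate top,
# negative for cells that overshot it. rel_pos rescales each cell between
# the two curved boundaries (0 = cp top, 1 = ventricle), so equal bins on
# rel_pos follow the curvature of the section.
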