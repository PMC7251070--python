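"""Signed distance to curved ROIs, relative position, curvature-conforming bins.

Distances are computed in 2D (x, y) from the 3D center of mass: ROIs are
drawn on the section plane and the ~12 μm of z depth is negligible against
hundreds of μm of migration.

Sign convention: the distance to an ROI is positive when the cell lies on the
same side of the curve as the *other* ROI's centroid, negative otherwise — a
cell that overshot the top of the cortical plate therefore gets a negative
distance to it, without assuming any global "up" axis.

Binning is on *relative position* between the two boundary curves
(0 at the cortical-plate top, 1 at the ventricle), so equal bins conform to
the actual curvature of the section instead of being straight rectangles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect3d import DetectedCell
from .io_formats import RoiPolyline

_EPS = 1e-12


def _closest_element(point: np.ndarray, roi: RoiPolyline) -> tuple[float, int, float, np.ndarray]:
    """Return (distance, segment index, parameter t, closest point)."""
    v = roi.vertices
    a, b = v[:-1], v[1:]
    d = b - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", point - a, d) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * d
    dist = np.hypot(*(point - proj).T)
    i = int(np.argmin(dist))
    return float(dist[i]), i, float(t[i]), proj[i]


def distance_to_roi(point, roi: RoiPolyline) -> float:
    """Minimum Euclidean distance (μm) from a 2D point to the polyline."""
    p = np.asarray(point, dtype=float)
    dist, _, _, _ = _closest_element(p, roi)
    return dist


def _local_direction(roi: RoiPolyline, seg: int, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Direction of the closest element and its anchor point.

    Interior of a segment → the segment direction. A shared vertex → the
    angle-bisector of the two incident segments, which resolves the side
    consistently inside the wedge of normals at a corner.
    """
    v = roi.vertices
    n_seg = len(v) - 1

    def unit(vec: np.ndarray) -> np.ndarray:
        return vec / np.linalg.norm(vec)

    if t <= _EPS and seg > 0:
        vert = v[seg]
        direction = unit(unit(v[seg] - v[seg - 1]) + unit(v[seg + 1] - v[seg]))
    elif t >= 1 - _EPS and seg < n_seg - 1:
        vert = v[seg + 1]
        direction = unit(unit(v[seg + 1] - v[seg]) + unit(v[seg + 2] - v[seg + 1]))
    else:
        vert = v[seg] + t * (v[seg + 1] - v[seg])
        direction = unit(v[seg + 1] - v[seg])
    return direction, vert


def signed_distance(point, roi: RoiPolyline, reference_point) -> float:
    """Distance to the curve, positive on the reference point's side.

    ``reference_point`` is normally the centroid of the opposite boundary
    (ventricle when measuring to the cortical-plate top and vice versa).
    """
    p = np.asarray(point, dtype=float)
    ref = np.asarray(reference_point, dtype=float)
    dist, seg, t, _ = _closest_element(p, roi)
    direction, anchor = _local_direction(roi, seg, t)

    def cross2(u: np.ndarray, v: np.ndarray) -> float:
        return float(u[0] * v[1] - u[1] * v[0])

    cross_p = cross2(direction, p - anchor)
    # side of the reference w.r.t. the same local element
    rdist, rseg, rt, _ = _closest_element(ref, roi)
    if rdist <= _EPS:
        raise ValueError("reference point lies on the ROI; sign undefined")
    rdir, ranchor = _local_direction(roi, rseg, rt)
    cross_r = cross2(rdir, ref - ranchor)

    if dist <= _EPS or cross_p == 0.0:
        return 0.0
    return dist if np.sign(cross_p) == np.sign(cross_r) else -dist


def relative_position(dist_cp: float, dist_vent: float) -> tuple[float, bool]:
    """Relative position in [0, 1]: 0 at the cortical-plate top, 1 at the
    ventricle. Cells beyond a boundary (negative distance) clamp to that
    boundary and carry an out-of-band flag."""
    if dist_cp < 0 and dist_vent < 0:
        raise ValueError("negative distance to both ROIs: geometrically inconsistent")
    if dist_cp < 0:
        return 0.0, True
    if dist_vent < 0:
        return 1.0, True
    total = dist_cp + dist_vent
    if total == 0:
        raise ValueError("point equidistant at zero from both ROIs")
    return dist_cp / total, False


def assign_bins(rel_pos, n_bins: int, out_of_band=None) -> np.ndarray:
    """Half-open equal bins on relative position: bin i covers
    [i/n, (i+1)/n), the last bin closed at 1. Out-of-band cells land in the
    boundary bin on their side (0 beyond the cortical plate, n−1 beyond the
    ventricle) and keep their flag."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rp = np.atleast_1d(np.asarray(rel_pos, dtype=float))
    idx = np.floor(rp * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    if out_of_band is not None:
        flags = np.atleast_1d(np.asarray(out_of_band, dtype=bool))
        idx = np.where(flags & (rp <= 0.0), 0, idx)
        idx = np.where(flags & (rp >= 1.0), n_bins - 1, idx)
    return idx


@dataclass
class SliceResult:
    """All cells of one section with distances, relative positions, bins."""

    slice_id: str
    cells: list[DetectedCell]
    n_bins: int
    cp_roi_name: str = "cp_top"
    vent_roi_name: str = "ventricle"

    def frame(self) -> pd.DataFrame:
        from .io_formats import cells_to_frame

        return cells_to_frame(self.cells, self.slice_id)

    def bin_table(self, include_flagged: bool = False) -> pd.DataFrame:
        """Per-channel bin counts and percentages (percentages per channel
        sum to 100 whenever the channel has any cell)."""
        rows = []
        cells = [c for c in self.cells if include_flagged or not c.double_positive]
        for channel in sorted({c.channel for c in cells}):
            ch_cells = [c for c in cells if c.channel == channel]
            counts = np.zeros(self.n_bins, dtype=int)
            for c in ch_cells:
                counts[c.bin_index] += 1
            total = counts.sum()
            for b in range(self.n_bins):
                rows.append(
                    {
                        "slice_id": self.slice_id,
                        "channel": channel,
                        "bin_index": b,
                        "count": int(counts[b]),
                        "percent": 100.0 * counts[b] / total if total else 0.0,
                    }
                )
        return pd.DataFrame(rows, columns=["slice_id", "channel", "bin_index", "count", "percent"])


def annotate_cells(
    cells: list[DetectedCell],
    cp_roi: RoiPolyline,
    vent_roi: RoiPolyline,
    n_bins: int = 10,
) -> None:
    """Fill dist/rel_pos/bin fields of each cell in place."""
    cp_ref = vent_roi.centroid
    vent_ref = cp_roi.centroid
    for c in cells:
        xy = np.array(c.com_um[:2])
        c.dist_cp_um = signed_distance(xy, cp_roi, cp_ref)
        c.dist_vent_um = signed_distance(xy, vent_roi, vent_ref)
        c.rel_pos, c.out_of_band = relative_position(c.dist_cp_um, c.dist_vent_um)
        c.bin_index = int(assign_bins([c.rel_pos], n_bins, [c.out_of_band])[0])


def build_slice_result(
    slice_id: str,
    cells: list[DetectedCell],
    cp_roi: RoiPolyline,
    vent_roi: RoiPolyline,
    n_bins: int = 10,
) -> SliceResult:
    annotate_cells(cells, cp_roi, vent_roi, n_bins)
    return SliceResult(slice_id=slice_id, cells=cells, n_bins=n_bins,
                       cp_roi_name=cp_roi.name, vent_roi_name=vent_roi.name)
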