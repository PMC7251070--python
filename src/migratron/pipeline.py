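"""End-to-end analysis: stacks + ROIs → annotated cells, summaries, stats."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detect3d, geometry, preprocess, stats
from .io_formats import ImageStack, RoiPolyline
from .preprocess import PreprocessParams

log = logging.getLogger(__name__)


@dataclass
class DetectParams:
    min_voxels: int = 30
    max_voxels: int | None = None
    merge_radius_px: float = 4.0
    match_radius_um: float = 5.0
    brightness_threshold: float = 1000.0


def detect_channel(
    stack: ImageStack,
    pre_params: PreprocessParams,
    det_params: DetectParams,
) -> list[detect3d.DetectedCell]:
    """Preprocess one channel and measure its cell objects."""
    binary = preprocess.preprocess_channel(stack, pre_params)
    labels = detect3d.label_objects(binary.mask, merge_radius_px=det_params.merge_radius_px)
    return detect3d.measure(
        labels, stack, min_voxels=det_params.min_voxels, max_voxels=det_params.max_voxels
    )


def analyze_slice(
    slice_id: str,
    green: ImageStack,
    red: ImageStack,
    rois: list[RoiPolyline],
    pre_params: PreprocessParams | None = None,
    det_params: DetectParams | None = None,
    n_bins: int = 10,
    cp_roi_name: str = "cp_top",
    vent_roi_name: str = "ventricle",
) -> tuple[geometry.SliceResult, list]:
    """Full per-slice pipeline.

    preprocess → 3D object counting → double-positive exclusion → signed
    distances to both boundary ROIs → relative position → bins. Returns the
    SliceResult (all cells, flagged double positives included with their
    flag) and the flagged pair list for audit.
    """
    pre_params = pre_params or PreprocessParams()
    det_params = det_params or DetectParams()

    by_name = {r.name: r for r in rois}
    for needed in (cp_roi_name, vent_roi_name):
        if needed not in by_name:
            raise ValueError(f"slice {slice_id}: ROI '{needed}' missing (have {sorted(by_name)})")
    cp_roi, vent_roi = by_name[cp_roi_name], by_name[vent_roi_name]

    green_cells = detect_channel(green, pre_params, det_params)
    red_cells = detect_channel(red, pre_params, det_params)
    kept_g, kept_r, pairs = detect3d.filter_double_positive(
        green_cells,
        red_cells,
        match_radius_um=det_params.match_radius_um,
        brightness_threshold=det_params.brightness_threshold,
    )
    if not green_cells and not red_cells:
        log.warning("slice %s: no cells detected", slice_id)

    all_cells = green_cells + red_cells  # flags already set on pair members
    result = geometry.build_slice_result(
        slice_id, all_cells, cp_roi, vent_roi, n_bins=n_bins
    )
    result.cp_roi_name, result.vent_roi_name = cp_roi_name, vent_roi_name
    return result, pairs


def pairs_to_frame(pairs, slice_id: str) -> pd.DataFrame:
    rows = [
        {
            "slice_id": slice_id,
            "green_x_um": g.com_um[0],
            "green_y_um": g.com_um[1],
            "red_x_um": r.com_um[0],
            "red_y_um": r.com_um[1],
            "pair_distance_um": d,
            "green_brightness": g.brightness,
            "red_brightness": r.brightness,
        }
        for g, r, d in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "slice_id", "green_x_um", "green_y_um", "red_x_um", "red_y_um",
            "pair_distance_um", "green_brightness", "red_brightness",
        ],
    )


def analyze_experiment(results: list[geometry.SliceResult], brain_id: str = "") -> dict:
    """Summaries plus the paired color comparison across slices."""
    summaries = [stats.summarize_slice(r, brain_id=brain_id) for r in results]
    out: dict = {"summaries": summaries}
    complete = [s for s in summaries if s.complete]
    if len(complete) >= 2:
        out["anova"] = stats.paired_color_anova(summaries)
        out["internal_variance"] = stats.absolute_variance_internal(summaries)
    else:
        log.warning("fewer than 2 complete slices: paired statistics skipped")
    return out
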