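"""Image-stack and ROI input/output.

Reads multi-channel confocal z-stacks from TIFF with physical calibration
(μm per pixel in-plane, μm per optical section), reads region-of-interest
polylines from either ImageJ ``.roi``/``.zip`` files or a plain CSV dialect,
and writes per-cell measurement tables as CSV.

Coordinate conventions
----------------------
Pixel indices are 0-based and a pixel's *center* sits at ``index + 0.5`` in
pixel units, so the center of mass of a single lit pixel is its geometric
center. All stored geometry is in μm; the px→μm conversion happens exactly
once, at read time.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import _imagej_roi

log = logging.getLogger(__name__)

CHANNEL_LABELS = ("green", "red", "dapi")

#: column order of the per-cell CSV
CELL_COLUMNS = [
    "slice_id",
    "channel",
    "x_um",
    "y_um",
    "z_um",
    "brightness",
    "voxel_count",
    "dist_cp_um",
    "dist_vent_um",
    "rel_pos",
    "bin_index",
    "double_positive_flag",
]


@dataclass
class ImageStack:
    """One channel's 3D voxel grid (z, y, x) with physical calibration."""

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_label: str
    bit_max: int = 65535

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a non-empty 3D (z, y, x) array")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be positive, got {self.z_step_um}")
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(f"channel_label must be one of {CHANNEL_LABELS}")
        vmin, vmax = self.voxels.min(), self.voxels.max()
        if vmin < 0 or vmax > self.bit_max:
            raise ValueError(f"intensities outside [0, {self.bit_max}]: [{vmin}, {vmax}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RoiPolyline:
    """Ordered open 2D vertex chain in μm naming an anatomical boundary."""

    name: str
    vertices: np.ndarray  # (n, 2) of (x, y) μm
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError(f"ROI '{self.name}' needs >= 2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"ROI '{self.name}' has non-finite vertices")
        if np.any(np.all(v[1:] == v[:-1], axis=1)):
            raise ValueError(f"ROI '{self.name}' has consecutive duplicate vertices")
        self.vertices = v

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def write_stack(
    path: str | Path,
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
    z_step_um: float,
) -> None:
    """Write channels (each (z, y, x) uint16) as an ImageJ-style ZCYX TIFF."""
    labels = list(channels)
    data = np.stack([np.asarray(channels[c], dtype=np.uint16) for c in labels], axis=1)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata={
            "axes": "ZCYX",
            "spacing": z_step_um,
            "unit": "um",
            "Labels": labels,
        },
    )


def _read_calibration(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    pixel = None
    z_step = None
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is not None:
        num, den = tag.value
        if num:
            pixel = den / num
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        z_step = float(meta["spacing"])
    return pixel, z_step


def read_stack(
    path: str | Path,
    channel_map: dict[int, str],
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> list[ImageStack]:
    """Read mapped channels of a multi-channel TIFF as ImageStacks.

    ``channel_map`` maps file channel index → channel label. Calibration
    precedence is explicit argument > TIFF metadata > error: a silent default
    would hide unit bugs.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    with tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_pixel, meta_z = _read_calibration(tif)

    # normalise to (C, Z, Y, X)
    if "C" not in axes:
        data = data[np.newaxis]
        axes = "C" + axes
    if "Z" not in axes:
        data = np.expand_dims(data, axes.index("C") + 1)
        axes = axes.replace("C", "CZ", 1)
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    pixel = pixel_size_um if pixel_size_um is not None else meta_pixel
    z_step = z_step_um if z_step_um is not None else meta_z
    if pixel is None:
        raise ValueError(f"{path}: pixel_size_um not in metadata and no override given")
    if z_step is None:
        raise ValueError(f"{path}: z_step_um not in metadata and no override given")
    if pixel_size_um is None or z_step_um is None:
        log.info("%s: calibration from TIFF metadata (%.4g um/px, %.4g um/z)", path, pixel, z_step)

    stacks = []
    for idx, label in channel_map.items():
        if not 0 <= idx < data.shape[0]:
            raise ValueError(
                f"{path}: channel index {idx} out of range for {data.shape[0]}-channel file"
            )
        stacks.append(
            ImageStack(
                voxels=data[idx],
                pixel_size_um=float(pixel),
                z_step_um=float(z_step),
                channel_label=label,
            )
        )
    return stacks


# ---------------------------------------------------------------------------
# ROI input
# ---------------------------------------------------------------------------

ROI_CSV_COLUMNS = ["name", "vertex_index", "x_um", "y_um"]


def read_rois(path: str | Path, pixel_size_um: float | None = None) -> list[RoiPolyline]:
    """Read polyline ROIs from ImageJ ``.roi``/``.zip`` or the CSV dialect.

    ImageJ files store pixel coordinates; ``pixel_size_um`` is required to
    convert them to μm. The CSV dialect (columns name, vertex_index, x_um,
    y_um) is already in μm.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        rois = _read_rois_csv(path)
    elif suffix in (".roi", ".zip"):
        if pixel_size_um is None or pixel_size_um <= 0:
            raise ValueError("reading ImageJ ROI files requires a positive pixel_size_um")
        rois = [
            RoiPolyline(name=name, vertices=np.asarray(pts, dtype=float) * pixel_size_um)
            for name, pts in _imagej_roi.read_roi_file(path)
        ]
    else:
        raise ValueError(f"unknown ROI format: {path.name} (expected .csv, .roi or .zip)")
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate ROI names in {path}: {names}")
    return rois


def _read_rois_csv(path: Path) -> list[RoiPolyline]:
    df = pd.read_csv(path)
    missing = set(ROI_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV {path} missing columns {sorted(missing)}")
    rois = []
    for name, grp in df.groupby("name", sort=False):
        grp = grp.sort_values("vertex_index")
        rois.append(RoiPolyline(name=str(name), vertices=grp[["x_um", "y_um"]].to_numpy()))
    return rois


def write_rois_csv(path: str | Path, rois: list[RoiPolyline]) -> None:
    rows = []
    for roi in rois:
        for i, (x, y) in enumerate(roi.vertices):
            rows.append({"name": roi.name, "vertex_index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=ROI_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------


def cells_to_frame(cells, slice_id: str) -> pd.DataFrame:
    """Flatten measured cells (with geometry annotations) to a tidy frame."""
    rows = []
    for c in cells:
        rows.append(
            {
                "slice_id": slice_id,
                "channel": c.channel,
                "x_um": c.com_um[0],
                "y_um": c.com_um[1],
                "z_um": c.com_um[2],
                "brightness": c.brightness,
                "voxel_count": c.voxel_count,
                "dist_cp_um": getattr(c, "dist_cp_um", np.nan),
                "dist_vent_um": getattr(c, "dist_vent_um", np.nan),
                "rel_pos": getattr(c, "rel_pos", np.nan),
                "bin_index": getattr(c, "bin_index", -1),
                "double_positive_flag": bool(c.double_positive),
            }
        )
    df = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return df.sort_values(["channel", "y_um", "x_um"], kind="mergesort").reset_index(drop=True)


def write_cells(cells, slice_id: str, path: str | Path) -> pd.DataFrame:
    """Write one slice's cells as CSV (one row per cell, stable order)."""
    df = cells_to_frame(cells, slice_id)
    df.to_csv(path, index=False)
    return df


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
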