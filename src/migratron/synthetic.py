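"""Synthetic two-channel cortical sections with known ground truth.

The generator emulates the data regime this pipeline is built for: two
intermingled cell populations (green control, red experimental) rendered as
Gaussian soma-sized blobs spanning a few optical sections, placed between two
concentric curved boundaries standing in for the top of the cortical plate
and the ventricular surface. Each cell's migration state is its distance
from the cortical-plate top along the local inward normal, drawn from a
truncated normal; a per-slice random offset shared by both colors emulates
developmental gradients along the rostro-caudal/medio-lateral axes. Poisson
photon noise plus Gaussian read noise on a 16-bit scale; optional co-located
double-positive cells rendered in both channels.

Ground truth is recorded before rendering, and stored distances are computed
against the *realized* boundary polylines, so re-deriving them from the
stored centers reproduces them exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import signed_distance
from .io_formats import ImageStack, RoiPolyline


@dataclass
class SceneParams:
    """Everything that defines one synthetic section (and its seed)."""

    image_shape: tuple[int, int, int] = (12, 1248, 1600)  # (z, y, x) px
    pixel_size_um: float = 0.5
    z_step_um: float = 1.0
    # concentric arcs: cortical-plate top (outer) and ventricle (inner)
    arc_center_um: tuple[float, float] = (400.0, 1600.0)  # (x, y)
    cp_radius_um: float = 1560.0
    vent_radius_um: float = 1060.0
    roi_vertex_spacing_um: float = 2.0
    n_cells: int = 300  # per channel (double positives counted in both)
    migration_mean_um: dict = field(default_factory=lambda: {"green": 150.0, "red": 150.0})
    migration_sd_um: dict = field(default_factory=lambda: {"green": 60.0, "red": 60.0})
    band_margin_um: float = 10.0
    soma_radius_um_mean: float = 4.0
    soma_radius_um_sd: float = 0.5
    peak_intensity_mean: float = 8000.0
    peak_intensity_sd: float = 2000.0
    background_level: float = 200.0
    read_noise_sd: float = 30.0
    double_positive_fraction: float = 0.01
    slice_offset_sd_um: float = 50.0
    min_spacing_factor: float = 1.5  # × soma diameter; 0 = crowding mode
    seed: int = 0

    @property
    def band_width_um(self) -> float:
        return self.cp_radius_um - self.vent_radius_um

    def validate(self) -> None:
        if self.cp_radius_um <= self.vent_radius_um:
            raise ValueError("cp_radius_um must exceed vent_radius_um (non-intersecting arcs)")
        lo, hi = self.band_margin_um, self.band_width_um - self.band_margin_um
        if hi <= lo:
            raise ValueError(
                f"band too narrow for placement: usable depth [{lo}, {hi}] um is empty"
            )
        for ch in ("green", "red"):
            if self.migration_sd_um[ch] <= 0:
                raise ValueError("migration_sd_um must be positive")
            if not lo - 3 * self.migration_sd_um[ch] < self.migration_mean_um[ch] < hi + 3 * self.migration_sd_um[ch]:
                raise ValueError(
                    f"band too narrow for the requested {ch} migration distribution "
                    f"(mean {self.migration_mean_um[ch]} um vs usable [{lo}, {hi}] um)"
                )


@dataclass
class GroundTruth:
    """True per-cell records plus the realized slice-level offset."""

    cells: pd.DataFrame  # channel, x_um, y_um, z_um, dist_cp_um, brightness, is_double_positive
    slice_offset_um: float = 0.0

    def per_channel(self, channel: str, include_double_positive: bool = True) -> pd.DataFrame:
        df = self.cells[self.cells["channel"] == channel]
        if not include_double_positive:
            df = df[~df["is_double_positive"]]
        return df.reset_index(drop=True)


def _arc_polyline(params: SceneParams, radius: float, name: str, extra_span: float = 0.03) -> RoiPolyline:
    cx, cy = params.arc_center_um
    phi_max = _placement_half_angle(params) + extra_span
    n = max(2, int(math.ceil(2 * phi_max * radius / params.roi_vertex_spacing_um)) + 1)
    phi = np.linspace(-phi_max, phi_max, n)
    x = cx + radius * np.sin(phi)
    y = cy - radius * np.cos(phi)
    return RoiPolyline(name=name, vertices=np.column_stack([x, y]))


def _placement_half_angle(params: SceneParams) -> float:
    x_extent = params.image_shape[2] * params.pixel_size_um
    margin = 4 * params.soma_radius_um_mean
    return math.asin(max(0.05, (x_extent / 2 - margin)) / params.cp_radius_um)


def make_rois(params: SceneParams) -> tuple[RoiPolyline, RoiPolyline]:
    cp = _arc_polyline(params, params.cp_radius_um, "cp_top")
    vent = _arc_polyline(params, params.vent_radius_um, "ventricle")
    return cp, vent


def _sample_positions(
    params: SceneParams, rng: np.random.Generator, slice_offset_um: float
) -> pd.DataFrame:
    """Sample channel, (x, y) μm and nominal migration depth for every cell."""
    lo = params.band_margin_um
    hi = params.band_width_um - params.band_margin_um
    phi_max = _placement_half_angle(params)
    n_dp = int(round(params.double_positive_fraction * params.n_cells))
    # double positives are shared cells counted in both channels
    plan = [("dp", n_dp), ("green", params.n_cells - n_dp), ("red", params.n_cells - n_dp)]

    min_spacing = params.min_spacing_factor * 2 * params.soma_radius_um_mean
    accepted: list[np.ndarray] = []
    rows = []
    for kind, count in plan:
        ch = "green" if kind == "dp" else kind
        mean = params.migration_mean_um[ch] + slice_offset_um
        sd = params.migration_sd_um[ch]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        if b <= a:
            raise ValueError("band too narrow for requested migration distribution")
        placed = 0
        attempts = 0
        max_attempts = 400 * max(count, 1)
        while placed < count:
            if attempts > max_attempts:
                raise ValueError(
                    "could not place cells at the requested spacing: band too crowded"
                )
            attempts += 1
            depth = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
            phi = rng.uniform(-phi_max, phi_max)
            r = params.cp_radius_um - depth
            x = params.arc_center_um[0] + r * math.sin(phi)
            y = params.arc_center_um[1] - r * math.cos(phi)
            p = np.array([x, y])
            if min_spacing > 0 and accepted:
                d2 = np.sum((np.array(accepted) - p) ** 2, axis=1)
                if d2.min() < min_spacing**2:
                    continue
            accepted.append(p)
            rows.append({"kind": kind, "x_um": x, "y_um": y, "depth_um": depth})
            placed += 1
    return pd.DataFrame(rows)


def _render_cell(
    canvas: np.ndarray,
    params: SceneParams,
    x_um: float,
    y_um: float,
    z_um: float,
    soma_radius_um: float,
    peak: float,
) -> None:
    px = params.pixel_size_um
    sigma_xy = (soma_radius_um / 1.5) / px  # px
    sigma_z = 0.9 / params.z_step_um  # in slices: blob visible over ~3-5 sections
    x0, y0 = x_um / px - 0.5, y_um / px - 0.5  # center in index units
    z0 = z_um / params.z_step_um - 0.5
    half = int(math.ceil(4 * sigma_xy))
    xa = max(0, int(math.floor(x0)) - half)
    xb = min(canvas.shape[2], int(math.ceil(x0)) + half + 1)
    ya = max(0, int(math.floor(y0)) - half)
    yb = min(canvas.shape[1], int(math.ceil(y0)) + half + 1)
    if xa >= xb or ya >= yb:
        return
    zz = np.arange(canvas.shape[0], dtype=np.float64)
    yy = np.arange(ya, yb, dtype=np.float64)
    xx = np.arange(xa, xb, dtype=np.float64)
    gz = np.exp(-0.5 * ((zz - z0) / sigma_z) ** 2)
    gy = np.exp(-0.5 * ((yy - y0) / sigma_xy) ** 2)
    gx = np.exp(-0.5 * ((xx - x0) / sigma_xy) ** 2)
    canvas[:, ya:yb, xa:xb] += peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def generate_slice(
    params: SceneParams,
) -> tuple[ImageStack, ImageStack, list[RoiPolyline], GroundTruth]:
    """Render one two-channel section; same seed + params → identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    cp, vent = make_rois(params)
    slice_offset = float(rng.normal(0.0, params.slice_offset_sd_um)) if params.slice_offset_sd_um > 0 else 0.0

    shape = params.image_shape
    clean = {ch: np.zeros(shape, dtype=np.float64) for ch in ("green", "red")}
    records = []

    if params.n_cells > 0:
        pos = _sample_positions(params, rng, slice_offset)
        z_lo = 2.5 * params.z_step_um
        z_hi = (shape[0] - 2.5) * params.z_step_um
        cp_ref = vent.centroid
        for _, row in pos.iterrows():
            z_um = float(rng.uniform(z_lo, z_hi))
            soma = max(1.5, float(rng.normal(params.soma_radius_um_mean, params.soma_radius_um_sd)))
            channels = ("green", "red") if row["kind"] == "dp" else (row["kind"],)
            dist_cp = signed_distance((row["x_um"], row["y_um"]), cp, cp_ref)
            for ch in channels:
                peak = max(2000.0, float(rng.normal(params.peak_intensity_mean, params.peak_intensity_sd)))
                _render_cell(clean[ch], params, row["x_um"], row["y_um"], z_um, soma, peak)
                records.append(
                    {
                        "channel": ch,
                        "x_um": row["x_um"],
                        "y_um": row["y_um"],
                        "z_um": z_um,
                        "dist_cp_um": dist_cp,
                        "brightness": peak,
                        "soma_radius_um": soma,
                        "is_double_positive": row["kind"] == "dp",
                    }
                )

    stacks = {}
    for ch in ("green", "red"):
        lam = clean[ch] + params.background_level
        img = rng.poisson(lam).astype(np.float64)
        if params.read_noise_sd > 0:
            img += rng.normal(0.0, params.read_noise_sd, size=shape)
        stacks[ch] = ImageStack(
            voxels=np.clip(np.round(img), 0, 65535).astype(np.uint16),
            pixel_size_um=params.pixel_size_um,
            z_step_um=params.z_step_um,
            channel_label=ch,
        )

    gt_cols = ["channel", "x_um", "y_um", "z_um", "dist_cp_um", "brightness",
               "soma_radius_um", "is_double_positive"]
    gt = GroundTruth(
        cells=pd.DataFrame(records, columns=gt_cols),
        slice_offset_um=slice_offset,
    )
    return stacks["green"], stacks["red"], [cp, vent], gt


# ---------------------------------------------------------------------------
# Experiment-level simulation
# ---------------------------------------------------------------------------


def sample_slice_distances(
    params: SceneParams,
    rng: np.random.Generator,
    delta_um: float = 0.0,
) -> dict[str, np.ndarray]:
    """Distance-level fast path: per-channel true migration distances of one
    slice, without rendering pixels. The red channel's mean is shifted by
    ``delta_um`` (a migration deficit leaves red cells farther from the
    cortical-plate top); the slice-level offset shifts both colors."""
    lo = params.band_margin_um
    hi = params.band_width_um - params.band_margin_um
    offset = float(rng.normal(0.0, params.slice_offset_sd_um)) if params.slice_offset_sd_um > 0 else 0.0
    out = {}
    for ch in ("green", "red"):
        mean = params.migration_mean_um[ch] + offset + (delta_um if ch == "red" else 0.0)
        sd = params.migration_sd_um[ch]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        if b <= a:
            raise ValueError("band too narrow for requested migration distribution")
        out[ch] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=params.n_cells, random_state=rng)
    return out


def generate_experiment(
    n_slices: int,
    delta_um: float = 0.0,
    seed: int = 0,
    params: SceneParams | None = None,
    render: bool = False,
):
    """Simulate one experiment of ``n_slices`` sections sharing parameters
    except for independent slice-level offsets.

    With ``render=False`` (the default) each bundle is the dict of true
    per-channel distances — sufficient for every statistical property, at a
    tiny fraction of the cost. With ``render=True`` each bundle is the full
    ``generate_slice`` output with the red mean shifted by ``delta_um``.
    """
    if n_slices < 2:
        raise ValueError("generate_experiment needs n_slices >= 2")
    base = params if params is not None else SceneParams()
    base.validate()
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(n_slices):
        if render:
            mig = dict(base.migration_mean_um)
            mig["red"] = mig["red"] + delta_um
            slice_params = replace(
                base,
                migration_mean_um=mig,
                migration_sd_um=dict(base.migration_sd_um),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            bundles.append(generate_slice(slice_params))
        else:
            bundles.append(sample_slice_distances(base, rng, delta_um=delta_um))
    return bundles


def distances_to_summaries(bundles: list[dict[str, np.ndarray]], brain_id: str = "") -> list:
    """Turn fast-path distance bundles into SliceSummary objects."""
    from .stats import SliceSummary

    out = []
    for i, b in enumerate(bundles):
        s = SliceSummary(slice_id=f"s{i}", brain_id=brain_id)
        for ch, d in b.items():
            d = np.asarray(d, dtype=float)
            s.n_cells[ch] = int(d.size)
            s.mean_dist_cp_um[ch] = float(d.mean()) if d.size else float("nan")
            s.sd_dist_cp_um[ch] = float(d.std(ddof=1)) if d.size > 1 else 0.0
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Ground-truth matching (benchmark helper)
# ---------------------------------------------------------------------------


def match_to_ground_truth(
    detected: list,
    truth: pd.DataFrame,
    match_radius_um: float,
    pixel_size_um: float,
) -> dict:
    """Greedy nearest-neighbour assignment of detections to true cells
    within ``match_radius_um`` (XY); reports recall, precision and the
    centroid RMSE in pixels over matched pairs."""
    if len(truth) == 0:
        return {"recall": float("nan"), "precision": float("nan"), "rmse_px": float("nan"),
                "n_matched": 0, "n_true": 0, "n_detected": len(detected)}
    det_xy = np.array([[c.com_um[0], c.com_um[1]] for c in detected]) if detected else np.empty((0, 2))
    true_xy = truth[["x_um", "y_um"]].to_numpy()
    pairs = []
    for i in range(det_xy.shape[0]):
        d = np.hypot(*(true_xy - det_xy[i]).T)
        for j in np.nonzero(d <= match_radius_um)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    errs = []
    for d, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errs.append(d)
    n_matched = len(errs)
    return {
        "recall": n_matched / len(truth),
        "precision": n_matched / det_xy.shape[0] if det_xy.shape[0] else float("nan"),
        "rmse_px": float(np.sqrt(np.mean(np.square(errs)))) / pixel_size_um if errs else float("nan"),
        "n_matched": n_matched,
        "n_true": int(len(truth)),
        "n_detected": int(det_xy.shape[0]),
    }
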