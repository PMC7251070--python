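import numpy as np
import pytest

from migratron import SceneParams


def small_scene(**overrides) -> SceneParams:
    """A geometrically coherent scaled-down section (160 x 200 um, 8 z) that
    the full pipeline resolves in under a second."""
    base = dict(
        image_shape=(8, 320, 400),
        pixel_size_um=0.5,
        z_step_um=1.0,
        arc_center_um=(100.0, 500.0),
        cp_radius_um=470.0,
        vent_radius_um=350.0,
        migration_mean_um={"green": 50.0, "red": 50.0},
        migration_sd_um={"green": 25.0, "red": 25.0},
        n_cells=20,
        double_positive_fraction=0.0,
        slice_offset_sd_um=0.0,
        seed=7,
    )
    base.update(overrides)
    return SceneParams(**base)


@pytest.fixture
def small_scene_params() -> SceneParams:
    return small_scene()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def gaussian_blob_stack(shape, centers, sigma_xy=4.0, sigma_z=1.0, peak=8000.0, background=200.0):
    """Noise-free stack of Gaussian blobs at (z, y, x) centers, uint16."""
    zz, yy, xx = np.indices(shape, dtype=float)
    img = np.full(shape, background, dtype=float)
    for cz, cy, cx in centers:
        img += peak * np.exp(
            -0.5 * (((zz - cz) / sigma_z) ** 2 + ((yy - cy) / sigma_xy) ** 2 + ((xx - cx) / sigma_xy) ** 2)
        )
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def flood_fill_count(mask: np.ndarray, connectivity_3d: bool = True) -> int:
    """Independent connected-component counter: breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    if mask.ndim == 2:
        mask = mask[None]
        seen = seen[None]
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    if not connectivity_3d:
        offsets = [(0, dy, dx) for dz, dy, dx in offsets if dz == 0]
    count = 0
    Z, Y, X = mask.shape
    for z0, y0, x0 in zip(*np.nonzero(mask)):
        if seen[z0, y0, x0]:
            continue
        count += 1
        stack = [(z0, y0, x0)]
        seen[z0, y0, x0] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X:
                    if mask[nz, ny, nx] and not seen[nz, ny, nx]:
                        seen[nz, ny, nx] = True
                        stack.append((nz, ny, nx))
    return count
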