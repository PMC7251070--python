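"""Independent oracles shared across test modules: brute-force geometry,
hand-computed ANOVA sums of squares, region growing for watershed checks."""
import numpy as np
from scipy import stats as sps

from migratron import RoiPolyline, SliceSummary


def dense_sample_distance(point, roi, samples_per_segment=20000):
    """Brute-force oracle: min distance to densely sampled polyline points."""
    p = np.asarray(point, dtype=float)
    best = np.inf
    v = roi.vertices
    for a, b in zip(v[:-1], v[1:]):
        t = np.linspace(0.0, 1.0, samples_per_segment)
        pts = a + t[:, None] * (b - a)
        best = min(best, float(np.hypot(*(pts - p).T).min()))
    return best


def random_polyline(rng, n_vertices=20, scale=100.0):
    # random walk avoids consecutive duplicates
    steps = rng.uniform(-1, 1, size=(n_vertices, 2)) * scale / n_vertices
    steps[np.all(steps == 0, axis=1)] = 0.1
    return RoiPolyline("r", np.cumsum(steps, axis=0) + rng.uniform(0, scale, 2))


def two_seed_region_growing(mask2d, seeds):
    """Simultaneous geodesic growth from seeds: watershed partition oracle."""
    from collections import deque

    labels = np.zeros(mask2d.shape, dtype=int)
    q = deque()
    for k, (y, x) in enumerate(seeds, start=1):
        labels[y, x] = k
        q.append((y, x))
    while q:
        y, x = q.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < mask2d.shape[0] and 0 <= nx < mask2d.shape[1]:
                if mask2d[ny, nx] and labels[ny, nx] == 0:
                    labels[ny, nx] = labels[y, x]
                    q.append((ny, nx))
    return labels


def dumbbell_mask(radius=10, sep=None):
    """Two overlapping discs (one connected component) plus their centers."""
    sep = sep if sep is not None else int(3 * radius)
    h, w = 4 * radius, 6 * radius + sep
    yy, xx = np.indices((h, w))
    c1 = (2 * radius, 2 * radius)
    c2 = (2 * radius, 2 * radius + sep)
    m = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= radius**2) | (
        (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= radius**2
    )
    return m[None], (c1, c2)


def hand_anova_color_f(values):
    """Balanced two-way ANOVA without replication from explicit sums of
    squares; rows are colors, columns slices."""
    y = np.asarray(values, dtype=float)
    grand = y.mean()
    n_c, n_s = y.shape
    ss_color = n_s * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_slice = n_c * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_resid = ss_total - ss_color - ss_slice
    df_c, df_r = n_c - 1, (n_c - 1) * (n_s - 1)
    f = (ss_color / df_c) / (ss_resid / df_r)
    return f, sps.f.sf(f, df_c, df_r)


def make_summary(slice_id, green, red, n=50, brain="b0"):
    s = SliceSummary(slice_id=slice_id, brain_id=brain)
    for color, mean in (("green", green), ("red", red)):
        s.n_cells[color] = n
        s.mean_dist_cp_um[color] = float(mean) if mean is not None else float("nan")
        s.sd_dist_cp_um[color] = 10.0 if mean is not None else float("nan")
    return s
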