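import itertools

import numpy as np
import pytest

from migratron import DetectedCell, ImageStack, filter_double_positive, label_objects, measure
from .conftest import flood_fill_count


def _stack(voxels, px=1.0, z_step=1.0, channel="green"):
    return ImageStack(np.asarray(voxels, dtype=np.uint16), pixel_size_um=px,
                      z_step_um=z_step, channel_label=channel)


class TestLabelObjects:
    def test_blob_spanning_slices_is_one_cell(self):
        mask = np.zeros((12, 20, 20), dtype=bool)
        for z in range(3, 8):
            mask[z, 8:13, 8:13] = True
        labels = label_objects(mask)
        assert labels.max() == 1

    def test_gap_of_six_slices_stays_two_cells(self):
        # oracle: plain 26-connectivity labeling; the centroid merge only
        # spans *adjacent* slices, so a 6-slice gap cannot bridge
        mask = np.zeros((12, 20, 20), dtype=bool)
        mask[2, 8:12, 8:12] = True
        mask[9, 8:12, 8:12] = True
        labels = label_objects(mask, merge_radius_px=4)
        assert labels.max() == 2 == flood_fill_count(mask)

    def test_adjacent_slice_centroid_merge(self):
        # no voxel contact (26-connectivity sees two objects), centroids
        # 2 px apart in adjacent slices -> merged by the centroid rule
        mask = np.zeros((4, 21, 21), dtype=bool)
        mask[1, 5, 5] = True  # centroid (5.5, 5.5)
        mask[2, 5, 7] = True  # centroid (5.5, 7.5): 2 px away, 1 empty column
        assert flood_fill_count(mask) == 2  # brute-force: distinct components
        labels = label_objects(mask, merge_radius_px=4)
        assert labels.max() == 1

    def test_centroid_merge_respects_radius(self):
        mask = np.zeros((4, 40, 40), dtype=bool)
        mask[1, 5:8, 5:8] = True  # centroid (6.5, 6.5)
        mask[2, 25:28, 25:28] = True  # centroid (26.5, 26.5): far
        labels = label_objects(mask, merge_radius_px=4)
        assert labels.max() == 2

    def test_conservation_every_voxel_labeled(self, rng):
        mask = rng.random((6, 40, 40)) > 0.7
        labels = label_objects(mask)
        np.testing.assert_array_equal(labels > 0, mask)


class TestMeasure:
    def test_single_voxel_pixel_center_convention(self):
        vox = np.zeros((2, 8, 12), dtype=np.uint16)
        vox[0, 4, 9] = 1000
        labels = (vox > 0).astype(np.int32)
        (cell,) = measure(labels, _stack(vox), min_voxels=1)
        assert cell.com_um == pytest.approx((9.5, 4.5, 0.5))
        assert cell.brightness == 1000
        assert cell.voxel_count == 1

    def test_symmetric_uniform_blob_com_at_centroid(self):
        vox = np.zeros((5, 20, 20), dtype=np.uint16)
        vox[1:4, 5:10, 7:12] = 2000
        labels = (vox > 0).astype(np.int32)
        (cell,) = measure(labels, _stack(vox, px=2.0, z_step=1.5), min_voxels=1, max_voxels=10**6)
        assert cell.com_um == pytest.approx((2.0 * 9.5, 2.0 * 7.5, 1.5 * 2.5))

    def test_intensity_weighted_com(self):
        vox = np.zeros((1, 1, 4), dtype=np.uint16)
        vox[0, 0, 0], vox[0, 0, 3] = 3000, 1000
        labels = np.zeros_like(vox, dtype=np.int32)
        labels[0, 0, 0] = labels[0, 0, 3] = 1
        (cell,) = measure(labels, _stack(vox), min_voxels=1)
        # weighted x: (3000*0.5 + 1000*3.5)/4000 = 1.25
        assert cell.com_um[0] == pytest.approx(1.25)
        assert cell.brightness == pytest.approx(2000.0)

    def test_size_filter(self):
        vox = np.zeros((3, 20, 20), dtype=np.uint16)
        vox[1, 2:4, 2:7] = 500  # 10 voxels
        vox[1, 10:16, 10:16] = 500  # 36 voxels
        labels = np.zeros_like(vox, dtype=np.int32)
        labels[1, 2:4, 2:7] = 1
        labels[1, 10:16, 10:16] = 2
        cells = measure(labels, _stack(vox), min_voxels=30)
        assert len(cells) == 1 and cells[0].voxel_count == 36

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            measure(np.zeros((2, 3, 3), np.int32), _stack(np.zeros((2, 4, 4))), min_voxels=1)

    def test_relabel_invariance(self, rng):
        vox = rng.integers(100, 5000, size=(4, 30, 30)).astype(np.uint16)
        labels = np.zeros(vox.shape, dtype=np.int32)
        labels[1, 2:8, 2:8] = 1
        labels[2, 15:22, 15:22] = 2
        labels[0, 20:26, 2:8] = 3
        perm = labels.copy()
        perm[labels == 1], perm[labels == 2], perm[labels == 3] = 3, 1, 2
        a = measure(labels, _stack(vox), min_voxels=1)
        b = measure(perm, _stack(vox), min_voxels=1)
        key = lambda c: (c.com_um, c.brightness, c.voxel_count)
        assert sorted(map(key, a)) == sorted(map(key, b))


def _cell(channel, x, y, brightness=5000.0, cid=0):
    return DetectedCell(cell_id=cid, channel=channel, com_um=(x, y, 5.0),
                        brightness=brightness, voxel_count=60)


class TestDoublePositive:
    def test_colocated_bright_pair_flagged(self):
        g, r, pairs = filter_double_positive(
            [_cell("green", 0, 0)], [_cell("red", 2, 0)], match_radius_um=5, brightness_threshold=1000
        )
        assert g == [] and r == [] and len(pairs) == 1
        assert pairs[0][0].double_positive and pairs[0][1].double_positive

    def test_far_pair_not_flagged(self):
        g, r, pairs = filter_double_positive(
            [_cell("green", 0, 0)], [_cell("red", 20, 0)], match_radius_um=5, brightness_threshold=1000
        )
        assert len(g) == 1 and len(r) == 1 and pairs == []

    def test_dim_pair_not_flagged(self):
        g, r, pairs = filter_double_positive(
            [_cell("green", 0, 0, brightness=800)], [_cell("red", 1, 0)],
            match_radius_um=5, brightness_threshold=1000,
        )
        assert pairs == [] and len(g) == 1 and len(r) == 1

    def test_greedy_nearest_first_matches_brute_force(self):
        green = [_cell("green", 0, 0, cid=0)]
        red = [_cell("red", 3, 0, cid=1), _cell("red", 1, 0, cid=2)]
        g, r, pairs = filter_double_positive(green, red, match_radius_um=5, brightness_threshold=1000)
        # brute force over all matchings of size <= 1 pair per cell:
        # the greedy nearest-first result must pick the nearer red (x=1)
        best = min(
            ((abs(rc.com_um[0]), rc.cell_id) for rc in red),
        )
        assert len(pairs) == 1
        assert pairs[0][1].cell_id == best[1] == 2
        assert len(r) == 1 and r[0].cell_id == 1

    def test_each_cell_in_at_most_one_pair(self, rng):
        green = [_cell("green", x, 0, cid=i) for i, x in enumerate(rng.uniform(0, 30, 12))]
        red = [_cell("red", x, 0.5, cid=i) for i, x in enumerate(rng.uniform(0, 30, 12))]
        g, r, pairs = filter_double_positive(green, red, 5.0, 1000)
        gs = [p[0].cell_id for p in pairs]
        rs = [p[1].cell_id for p in pairs]
        assert len(gs) == len(set(gs)) and len(rs) == len(set(rs))
        assert len(g) + len(gs) == 12 and len(r) + len(rs) == 12

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            filter_double_positive([], [], match_radius_um=-1, brightness_threshold=1000)
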