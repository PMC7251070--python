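import numpy as np
import pytest
from scipy import stats as sps

from migratron import (
    SliceSummary,
    absolute_variance_internal,
    absolute_variance_matched,
    paired_color_anova,
    summarize_slice,
    two_sample_test,
)
from migratron.detect3d import DetectedCell
from migratron.geometry import SliceResult


from .oracles import hand_anova_color_f, make_summary


def _result(dists_by_color):
    cells = []
    i = 0
    for color, dists in dists_by_color.items():
        for d in dists:
            cells.append(DetectedCell(cell_id=i, channel=color, com_um=(0.0, 0.0, 5.0),
                                      brightness=4000.0, voxel_count=60, dist_cp_um=float(d)))
            i += 1
    return SliceResult(slice_id="s0", cells=cells, n_bins=10)


class TestSummarize:
    def test_mean_and_sd(self):
        s = summarize_slice(_result({"green": [100, 200, 300], "red": [50, 150]}))
        assert s.mean_dist_cp_um["green"] == pytest.approx(200.0)
        assert s.sd_dist_cp_um["green"] == pytest.approx(100.0)
        assert s.n_cells == {"green": 3, "red": 2}

    def test_missing_color_marked(self):
        s = summarize_slice(_result({"green": [100.0, 120.0]}))
        assert np.isnan(s.mean_dist_cp_um["red"]) and not s.complete
        assert s.has("green")

    def test_order_invariance(self, rng):
        d = list(rng.uniform(0, 300, 20))
        a = summarize_slice(_result({"green": d, "red": d[::-1]}))
        b = summarize_slice(_result({"green": d[::-1], "red": d}))
        assert a.mean_dist_cp_um == pytest.approx(b.mean_dist_cp_um)

    def test_double_positives_excluded(self):
        res = _result({"green": [100, 200]})
        res.cells[0].double_positive = True
        s = summarize_slice(res)
        assert s.n_cells["green"] == 1 and s.mean_dist_cp_um["green"] == 200.0


class TestPairedColorAnova:
    def test_identical_colors_give_f0_p1(self):
        summaries = [make_summary(f"s{i}", 100 + 10 * i, 100 + 10 * i) for i in range(4)]
        rep = paired_color_anova(summaries)
        assert rep.f_statistic == 0.0 and rep.p_value == 1.0
        assert rep.effect_color_um == 0.0

    def test_matches_hand_computed_table(self):
        green = [120.0, 150.0, 135.0]
        red = [100.0, 160.0, 120.0]
        summaries = [make_summary(f"s{i}", g, r) for i, (g, r) in enumerate(zip(green, red))]
        rep = paired_color_anova(summaries)
        f, p = hand_anova_color_f([green, red])
        assert rep.f_statistic == pytest.approx(f, rel=1e-9)
        assert rep.p_value == pytest.approx(p, rel=1e-9)
        assert rep.effect_color_um == pytest.approx(np.mean(np.array(green) - np.array(red)))

    def test_slice_shift_leaves_color_p_unchanged(self, rng):
        for _ in range(10):
            green = rng.uniform(80, 200, 5)
            red = rng.uniform(80, 200, 5)
            base = [make_summary(f"s{i}", g, r) for i, (g, r) in enumerate(zip(green, red))]
            shift = rng.uniform(-100, 100)
            shifted = [make_summary(f"s{i}", g + (shift if i == 2 else 0), r + (shift if i == 2 else 0))
                       for i, (g, r) in enumerate(zip(green, red))]
            assert paired_color_anova(shifted).p_value == pytest.approx(
                paired_color_anova(base).p_value, rel=1e-8
            )

    def test_incomplete_slices_dropped_and_too_few_rejected(self):
        summaries = [make_summary("s0", 100, 110), make_summary("s1", 100, None)]
        with pytest.raises(ValueError, match=">= 2"):
            paired_color_anova(summaries)


class TestAbsoluteVariance:
    def test_internal_arithmetic(self):
        summaries = [make_summary("s0", 110, 100), make_summary("s1", 100, 110)]
        out = absolute_variance_internal(summaries)
        assert out["abs_mean_um"] == pytest.approx(10.0)
        assert out["signed_mean_um"] == pytest.approx(0.0)

    def test_internal_null_case(self):
        summaries = [make_summary(f"s{i}", 100.0, 100.0) for i in range(3)]
        assert absolute_variance_internal(summaries)["abs_mean_um"] == 0.0

    def test_internal_matches_brute_force(self, rng):
        g, r = rng.uniform(50, 250, 8), rng.uniform(50, 250, 8)
        summaries = [make_summary(f"s{i}", gi, ri) for i, (gi, ri) in enumerate(zip(g, r))]
        out = absolute_variance_internal(summaries)
        assert out["abs_mean_um"] == pytest.approx(np.mean(np.abs(g - r)))
        assert out["signed_mean_um"] == pytest.approx(np.mean(g - r))
        assert out["abs_sem_um"] == pytest.approx(np.std(np.abs(g - r), ddof=1) / np.sqrt(8))

    def test_matched_self_comparison_is_zero(self):
        brain = [make_summary(f"s{i}", 100 + i, 110 + i) for i in range(5)]
        out = absolute_variance_matched(brain, brain, 0, 0)
        assert out["abs_mean_um"] == 0.0 and out["n_pairs"] == 5

    def test_matched_alignment_overlap(self):
        # brains of lengths 5 and 7, anchors at 1 and 3: enumerate overlap
        a = [make_summary(f"a{i}", 100 + i, 100 + i, brain="A") for i in range(5)]
        b = [make_summary(f"b{i}", 200 + i, 200 + i, brain="B") for i in range(7)]
        out = absolute_variance_matched(a, b, anchor_a=1, anchor_b=3)
        pos_a = {i - 1 for i in range(5)}  # {-1..3}
        pos_b = {i - 3 for i in range(7)}  # {-3..3}
        assert out["n_pairs"] == len(pos_a & pos_b) == 5

    def test_matched_pools_colors_by_cell_count(self):
        a = [make_summary("a0", 100, 200, n=10)]
        a[0].n_cells = {"green": 10, "red": 30}  # pooled = (10*100+30*200)/40 = 175
        b = [make_summary("b0", 175, 175)]
        out = absolute_variance_matched(a, b, 0, 0)
        assert out["abs_mean_um"] == pytest.approx(0.0)

    def test_no_overlap_rejected(self):
        a = [make_summary("a0", 1, 1)]
        b = [make_summary("b0", 1, 1), make_summary("b1", 1, 1)]
        with pytest.raises(ValueError, match="overlap"):
            absolute_variance_matched(a, b, anchor_a=0, anchor_b=2)


class TestTwoSampleTest:
    def test_identical_samples_p_one(self, rng):
        x = rng.normal(100, 10, 40)
        rep = two_sample_test(x, x.copy())
        assert rep.p_value == pytest.approx(1.0)

    def test_normal_samples_take_t_branch(self, rng):
        x, y = rng.normal(0, 1, 50), rng.normal(0.2, 1, 50)
        rep = two_sample_test(x, y)
        assert rep.test_name.startswith("t-test")
        assert rep.normality_decision["both_normal"]

    def test_heavy_tails_take_ks_branch_with_ecdf_oracle(self, rng):
        x = rng.standard_cauchy(80) * 50
        y = rng.standard_cauchy(80) * 50 + 5
        rep = two_sample_test(x, y)
        assert rep.test_name.startswith("KS")
        # brute-force max ECDF gap oracle
        grid = np.sort(np.concatenate([x, y]))
        ecdf = lambda s, g: np.searchsorted(np.sort(s), g, side="right") / s.size
        gap = np.max(np.abs(ecdf(x, grid) - ecdf(y, grid)))
        assert rep.statistic == pytest.approx(gap, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])
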