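"""Per-slice summaries and paired internal-control statistics.

The experimental design puts control (green) and experimental (red) cells in
the *same* tissue section, so the unit of comparison is the per-slice pair of
color means. That supports a two-way ANOVA with factors color and slice on
per-slice mean migration distances, where the reported p-value is the color
effect — variation between slices is absorbed by the slice factor instead of
inflating the error term, which is what makes the internal control more
powerful than matching sections across brains.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

log = logging.getLogger(__name__)

COLORS = ("green", "red")


@dataclass
class SliceSummary:
    """Per-slice per-color aggregates of distance to the cortical-plate top."""

    slice_id: str
    brain_id: str = ""
    n_cells: dict = field(default_factory=dict)  # color -> int
    mean_dist_cp_um: dict = field(default_factory=dict)  # color -> float
    sd_dist_cp_um: dict = field(default_factory=dict)  # color -> float

    def has(self, color: str) -> bool:
        return color in self.mean_dist_cp_um and not math.isnan(self.mean_dist_cp_um[color])

    @property
    def complete(self) -> bool:
        return all(self.has(c) for c in COLORS)

    def pooled_mean(self) -> float:
        """All-fluorescent-cells mean, pooling colors (used for matching
        sections across brains, where color identity is not comparable)."""
        n = sum(self.n_cells.get(c, 0) for c in COLORS if self.has(c))
        if n == 0:
            return float("nan")
        s = sum(self.n_cells[c] * self.mean_dist_cp_um[c] for c in COLORS if self.has(c))
        return s / n


@dataclass
class StatsReport:
    test_name: str
    p_value: float
    effect_color_um: float = float("nan")
    n_pairs: int = 0
    f_statistic: float = float("nan")
    statistic: float = float("nan")
    normality_decision: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


def summarize_slice(result, brain_id: str = "") -> SliceSummary:
    """Aggregate one slice's cells per color (double positives excluded)."""
    cells = [c for c in result.cells if not c.double_positive]
    summary = SliceSummary(slice_id=result.slice_id, brain_id=brain_id)
    for color in COLORS:
        d = np.array([c.dist_cp_um for c in cells if c.channel == color], dtype=float)
        summary.n_cells[color] = int(d.size)
        if d.size:
            summary.mean_dist_cp_um[color] = float(d.mean())
            summary.sd_dist_cp_um[color] = float(d.std(ddof=1)) if d.size > 1 else 0.0
        else:
            summary.mean_dist_cp_um[color] = float("nan")
            summary.sd_dist_cp_um[color] = float("nan")
            log.warning("slice %s: no %s cells, excluded from paired tests", result.slice_id, color)
    return summary


def _complete(summaries: list[SliceSummary]) -> list[SliceSummary]:
    out = [s for s in summaries if s.complete]
    dropped = len(summaries) - len(out)
    if dropped:
        log.info("dropped %d slice(s) missing a color from paired analysis", dropped)
    return out


def paired_color_anova(summaries: list[SliceSummary]) -> StatsReport:
    """Two-way ANOVA (color × slice) on per-slice per-color mean distances.

    One value per design cell (the per-slice color mean), matching a
    dot-per-slice presentation; the reported p is the color effect. The
    signed effect is the mean over slices of (green mean − red mean).
    """
    complete = _complete(summaries)
    if len(complete) < 2:
        raise ValueError("paired_color_anova needs >= 2 slices with both colors present")

    rows = [
        {"slice": s.slice_id, "color": c, "y": s.mean_dist_cp_um[c]}
        for s in complete
        for c in COLORS
    ]
    df = pd.DataFrame(rows)
    diffs = np.array([s.mean_dist_cp_um["green"] - s.mean_dist_cp_um["red"] for s in complete])
    effect = float(diffs.mean())

    scale = float(np.abs(df["y"]).max()) or 1.0
    if np.allclose(diffs, 0.0, atol=1e-12 * scale):
        # green ≡ red within every slice: zero color sum of squares
        return StatsReport(
            test_name="two-way ANOVA (color x slice)",
            p_value=1.0,
            effect_color_um=effect,
            n_pairs=len(complete),
            f_statistic=0.0,
            notes="zero within-slice color difference",
        )

    model = ols("y ~ C(color) + C(slice)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f = float(table.loc["C(color)", "F"])
    p = float(table.loc["C(color)", "PR(>F)"])
    return StatsReport(
        test_name="two-way ANOVA (color x slice)",
        p_value=p,
        effect_color_um=effect,
        n_pairs=len(complete),
        f_statistic=f,
    )


def absolute_variance_internal(summaries: list[SliceSummary]) -> dict:
    """Internal-control variability: per-slice |green mean − red mean|,
    aggregated as mean ± SEM; the signed green-minus-red mean is reported
    alongside (a color-bias estimate)."""
    complete = _complete(summaries)
    if not complete:
        raise ValueError("no complete slices")
    diffs = np.array([s.mean_dist_cp_um["green"] - s.mean_dist_cp_um["red"] for s in complete])
    return {
        "abs_mean_um": float(np.abs(diffs).mean()),
        "abs_sem_um": float(sps.sem(np.abs(diffs))) if diffs.size > 1 else 0.0,
        "signed_mean_um": float(diffs.mean()),
        "signed_sem_um": float(sps.sem(diffs)) if diffs.size > 1 else 0.0,
        "n_slices": int(diffs.size),
    }


def absolute_variance_matched(
    brain_a: list[SliceSummary],
    brain_b: list[SliceSummary],
    anchor_a: int = 0,
    anchor_b: int = 0,
) -> dict:
    """Section-matching variability between two brains.

    Slices are ordered by serial section index; each brain's anchor is the
    index of its landmark slice (e.g. the first with an uninterrupted corpus
    callosum), and slices are matched by position relative to the anchor.
    All fluorescent cells are pooled across colors within a slice. Unmatched
    positions are dropped and logged.
    """
    pos_a = {i - anchor_a: s for i, s in enumerate(brain_a)}
    pos_b = {i - anchor_b: s for i, s in enumerate(brain_b)}
    common = sorted(set(pos_a) & set(pos_b))
    common = [
        p for p in common
        if not math.isnan(pos_a[p].pooled_mean()) and not math.isnan(pos_b[p].pooled_mean())
    ]
    if not common:
        raise ValueError("no overlapping slice positions after alignment")
    dropped = len(brain_a) + len(brain_b) - 2 * len(common)
    if dropped:
        log.info("section matching dropped %d unmatched slice(s)", dropped)
    diffs = np.array([pos_a[p].pooled_mean() - pos_b[p].pooled_mean() for p in common])
    return {
        "abs_mean_um": float(np.abs(diffs).mean()),
        "abs_sem_um": float(sps.sem(np.abs(diffs))) if diffs.size > 1 else 0.0,
        "n_pairs": int(diffs.size),
        "positions": common,
    }


def two_sample_test(x, y, normality_alpha: float = 0.05) -> StatsReport:
    """Normality-gated two-sample comparison.

    Each sample is screened with a Kolmogorov–Smirnov normality test (against
    a normal with the sample's fitted mean and sd); if both pass at
    ``normality_alpha`` the comparison is a two-tailed t-test, otherwise a
    two-tailed two-sample KS test. The report records which branch fired.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("two_sample_test needs n >= 3 per sample")

    def ks_normal(sample: np.ndarray) -> float:
        sd = sample.std(ddof=1)
        if sd == 0:
            return 0.0  # degenerate sample is not normal
        return float(sps.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue)

    p_x, p_y = ks_normal(x), ks_normal(y)
    normal = p_x > normality_alpha and p_y > normality_alpha
    decision = {"x_ks_p": p_x, "y_ks_p": p_y, "both_normal": normal}
    if normal:
        res = sps.ttest_ind(x, y)
        return StatsReport(
            test_name="t-test (two-tailed)",
            p_value=float(res.pvalue),
            statistic=float(res.statistic),
            n_pairs=min(x.size, y.size),
            normality_decision=decision,
        )
    res = sps.ks_2samp(x, y)
    return StatsReport(
        test_name="KS test (two-tailed)",
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_pairs=min(x.size, y.size),
        normality_decision=decision,
    )


def summaries_to_frame(summaries: list[SliceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"slice_id": s.slice_id, "brain_id": s.brain_id}
        for c in COLORS:
            row[f"n_{c}"] = s.n_cells.get(c, 0)
            row[f"mean_dist_cp_{c}_um"] = s.mean_dist_cp_um.get(c, float("nan"))
            row[f"sd_dist_cp_{c}_um"] = s.sd_dist_cp_um.get(c, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_summaries(df: pd.DataFrame) -> list[SliceSummary]:
    out = []
    for _, row in df.iterrows():
        s = SliceSummary(slice_id=str(row["slice_id"]), brain_id=str(row.get("brain_id", "")))
        for c in COLORS:
            s.n_cells[c] = int(row[f"n_{c}"])
            s.mean_dist_cp_um[c] = float(row[f"mean_dist_cp_{c}_um"])
            s.sd_dist_cp_um[c] = float(row[f"sd_dist_cp_{c}_um"])
        out.append(s)
    return out
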