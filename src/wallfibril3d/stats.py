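"""Summary statistics and notched-boxplot group comparison.

The study compares measurement populations (fibril diameter, edge-to-edge
gap, cross-link length) between preparation protocols or genotypes with
notched boxplots: the notch spans ``median +/- 1.57 * IQR / sqrt(n)``, an
approximate 95% confidence interval for the median, and two groups are
called significantly different exactly when their notches do not overlap.
No further hypothesis test is layered on top — that is the study's
inference rule, reproduced as stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrology import AnalysisConfig, AnalysisROI, analyze_roi
from .volume import DensityVolume

__all__ = [
    "BoxplotStats",
    "GroupComparison",
    "boxplot_stats",
    "summarize",
    "notch_overlap_test",
    "threshold_sensitivity",
    "notched_boxplot_figure",
]

NOTCH_FACTOR = 1.57  # median +/- 1.57 IQR / sqrt(n): approx. 95% CI of the median


@dataclass
class BoxplotStats:
    """All quantities drawn in one notched box."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float    # smallest datum within 1.5 IQR below Q1
    whisker_high: float   # largest datum within 1.5 IQR above Q3
    notch_low: float
    notch_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class GroupComparison:
    stats_a: BoxplotStats
    stats_b: BoxplotStats
    notch_overlap: bool
    verdict: str  # {"significant", "not_significant"}


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles by linear interpolation of order statistics (positions
    ``1 + (n-1) p``), Tukey whiskers, and the notch formula above."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats: empty input")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    half_notch = NOTCH_FACTOR * iqr / np.sqrt(v.size)
    return BoxplotStats(
        n=int(v.size),
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        notch_low=float(med - half_notch),
        notch_high=float(med + half_notch),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    )


def summarize(values) -> dict:
    """mean +/- sample SD (n-1), range, n — the study's reporting style."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize: empty input")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    out = dict(mean=float(v.mean()), sd=sd, min=float(v.min()),
               max=float(v.max()), n=int(v.size))
    out["report"] = (f"{out['mean']:.1f}±{out['sd']:.1f} nm "
                     f"(range {out['min']:.1f}–{out['max']:.1f} nm, n = {out['n']})")
    return out


def notch_overlap_test(a, b) -> GroupComparison:
    """Two groups differ significantly iff their notch intervals are
    disjoint."""
    sa, sb = boxplot_stats(a), boxplot_stats(b)
    disjoint = sa.notch_high < sb.notch_low or sb.notch_high < sa.notch_low
    return GroupComparison(
        stats_a=sa, stats_b=sb, notch_overlap=not disjoint,
        verdict="significant" if disjoint else "not_significant")


def threshold_sensitivity(vol: DensityVolume, roi: AnalysisROI,
                          config: AnalysisConfig,
                          deltas=(-0.15, -0.05, 0.0, 0.05, 0.15)) -> pd.DataFrame:
    """Re-run the per-ROI analysis with the segmentation threshold offset
    by each delta (SD units) and report the shift of every mean
    measurement relative to delta = 0.

    The delta = 0 run is the reference analysis itself (bit-identical).
    """
    deltas = list(deltas)
    if 0.0 not in deltas:
        raise ValueError("deltas must include 0")
    # resolve the auto threshold once so every delta offsets the same base
    base_cfg = _copy_config(config)
    rows = []
    ref: dict[str, float] = {}
    results = {}
    for d in sorted(set(deltas)):
        cfg = _copy_config(base_cfg)
        cfg.delta = float(d)
        try:
            table, prov = analyze_roi(vol, roi, cfg)
        except RuntimeError as exc:
            rows.append(dict(delta=d, flagged=str(exc)))
            continue
        means = table.groupby("type")["value_nm"].mean().to_dict()
        counts = table.groupby("type")["value_nm"].count().to_dict()
        results[d] = dict(
            delta=d, threshold=prov.get("threshold"),
            mean_diameter=means.get("diameter", np.nan),
            mean_edge_gap=means.get("edge_gap", np.nan),
            mean_crosslink=means.get("crosslink_len", np.nan),
            n_diameter=counts.get("diameter", 0),
            flagged="" if counts.get("diameter", 0) else "empty",
        )
    base = results.get(0.0, {})
    for d in sorted(results):
        r = dict(results[d])
        for key in ("mean_diameter", "mean_edge_gap", "mean_crosslink"):
            r[key.replace("mean_", "shift_")] = (
                r[key] - base.get(key, np.nan) if base else np.nan)
        rows.append(r)
    return pd.DataFrame(rows)


def _copy_config(config: AnalysisConfig) -> AnalysisConfig:
    import copy

    return copy.deepcopy(config)


def notched_boxplot_figure(groups: dict[str, np.ndarray], ylabel: str,
                           path=None):
    """Notched box-and-whisker figure in the style of the study's
    comparison panels (median band, notch, mean diamond, outlier circles)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.6 + 1.1 * len(labels), 4.0))
    ax.boxplot(data, notch=True, bootstrap=None, showmeans=True,
               meanprops=dict(marker="D", markerfacecolor="black",
                              markeredgecolor="black", markersize=5),
               flierprops=dict(marker="o", markerfacecolor="none",
                               markersize=4),
               tick_labels=labels)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
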