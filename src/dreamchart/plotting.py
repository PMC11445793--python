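"""Dream-chart plots: windowed valence line, shaded peaks/troughs,
optional mini-trapezoid verticals and trendline overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .segmentation import Segmentation
from .trend import TrendFit
from .windowing import DreamChart

__all__ = ["plot_chart"]

PEAK_COLOR = "#7b4fa6"  # purple
TROUGH_COLOR = "#e08214"  # orange


def plot_chart(
    chart: DreamChart,
    segmentation: Segmentation | None = None,
    trend: TrendFit | None = None,
    show_trapezoids: bool = False,
    ax: plt.Axes | None = None,
    savepath: str | Path | None = None,
):
    """Plot one dream chart.

    Draws the standardized valence series against the chronological axis
    with the zero midline; peaks are shaded purple and troughs orange, with
    optional vertical lines marking the mini-trapezoid edges and an optional
    polynomial trendline overlay.  Returns the matplotlib Axes; writes the
    figure to ``savepath`` (SVG/PNG by extension) when given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    ax.axhline(0.0, color="0.4", linewidth=0.8)
    ax.plot(chart.x, chart.y, color="0.15", linewidth=1.4, marker="o", markersize=2.5)

    if segmentation is not None:
        for seg in segmentation.segments:
            color = PEAK_COLOR if seg.kind == "peak" else TROUGH_COLOR
            ax.fill_between(
                seg.points[:, 0], seg.points[:, 1], 0.0, color=color, alpha=0.35, linewidth=0
            )
            if show_trapezoids:
                for px, py in seg.points:
                    ax.plot([px, px], [0.0, py], color=color, linewidth=0.6, alpha=0.8)

    if trend is not None and chart.n_windows > 1:
        xs = np.linspace(chart.x[0], chart.x[-1], 200)
        ax.plot(xs, trend.predict(xs), color="#2166ac", linewidth=1.6, linestyle="--",
                label=f"trend (deg {trend.degree}, $r^2$={trend.r_squared:.2f})")
        ax.legend(loc="best", fontsize=8)

    ax.set_xlabel("chronological position (window)")
    ax.set_ylabel("standardized valence")
    ax.set_title(f"dream chart: {chart.report_id}")
    if savepath is not None:
        ax.figure.savefig(savepath, bbox_inches="tight")
    return ax
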