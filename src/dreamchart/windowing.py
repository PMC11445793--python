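"""Sliding-window standardization of a valence series into a dream chart.

The report is divided into fixed-length windows (default 30 words,
overlapping by 29, i.e. stride 1).  Each window's valence ratings are
summed and divided by the report's window count, which controls for the
varying word counts of different dreams and undoes the flattening effect
that long runs of neutral words would otherwise have on the chart's peaks,
troughs and trendline.  The x-axis of the resulting chart is a uniformly
spaced chronological "time variable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ValenceSeries

__all__ = ["WindowConfig", "DreamChart", "make_chart"]

NORMALIZERS = ("n_windows", "window_length", "none")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters.

    window_length : tokens per window (default 30)
    overlap       : tokens shared by consecutive windows (default 29);
                    stride = window_length - overlap
    normalizer    : divisor applied to each window sum —
                    'n_windows' (the report's window count; default),
                    'window_length', or 'none'
    """

    window_length: int = 30
    overlap: int = 29
    normalizer: str = "n_windows"

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (1 <= self.overlap < self.window_length):
            raise ValueError("overlap must satisfy 1 <= overlap < window_length")
        if self.normalizer not in NORMALIZERS:
            raise ValueError(f"normalizer must be one of {NORMALIZERS}")

    @property
    def stride(self) -> int:
        return self.window_length - self.overlap


@dataclass(frozen=True)
class DreamChart:
    """The windowed, standardized valence series of one dream report.

    ``x`` is the uniformly spaced chronological axis (1 ... n_windows, unit
    spacing); ``y`` the standardized valence value of each window.
    """

    report_id: str
    x: np.ndarray
    y: np.ndarray
    n_windows: int
    raw_length: int

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) != len(y) or len(x) != self.n_windows:
            raise ValueError("x, y and n_windows are inconsistent")
        if self.n_windows < 1:
            raise ValueError("a chart needs at least one window")
        if not np.all(np.isfinite(y)):
            raise ValueError("chart values must be finite")
        if self.n_windows > 1 and not np.allclose(np.diff(x), np.diff(x)[0]):
            raise ValueError("x must be uniformly spaced")

    def __len__(self) -> int:
        return self.n_windows

    def to_frame(self) -> pd.DataFrame:
        """Chart as a tidy DataFrame with columns report_id, x, y."""
        return pd.DataFrame(
            {"report_id": self.report_id, "x": self.x, "y": self.y}
        )


def make_chart(series: ValenceSeries, cfg: WindowConfig | None = None) -> DreamChart:
    """Apply the sliding-window standardization to a valence series.

    Window k covers tokens k ... k + window_length - 1 (stride = window_length
    - overlap, 1 at defaults), so a report of L tokens yields
    W = max(1, L - window_length + stride) windows at stride 1.  Each window
    sum is divided by the configured normalizer (the window count W by
    default).  Reports shorter than one window collapse to a single window
    spanning the whole report.
    """
    cfg = cfg or WindowConfig()
    values = series.values
    L = len(values)

    if L < cfg.window_length:
        sums = np.array([values.sum()])
    else:
        csum = np.concatenate(([0.0], np.cumsum(values)))
        starts = np.arange(0, L - cfg.window_length + 1, cfg.stride)
        sums = csum[starts + cfg.window_length] - csum[starts]

    W = len(sums)
    if cfg.normalizer == "n_windows":
        y = sums / W
    elif cfg.normalizer == "window_length":
        y = sums / cfg.window_length
    else:
        y = sums
    x = np.arange(1, W + 1, dtype=float)
    return DreamChart(report_id=series.report_id, x=x, y=y, n_windows=W, raw_length=L)
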