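"""Peak and trough demarcation of a dream chart.

A peak starts at the first positive value above the zero midline and ends at
the first zero following the positive run; a trough is defined symmetrically
below the midline.  A chart may contain no, one, or several peaks and
troughs, and a peak or trough may consist of a single value.  Two
extensions make the zero-bounded definition total on real (floating-point)
charts:

* where consecutive values flip sign with no intervening zero, a synthetic
  boundary point is inserted at the linearly interpolated zero crossing,
  closing one segment and opening the next (this preserves area
  additivity);
* the chart's first and last points act as boundaries for segments the
  chart edges truncate.

Values with \\|y\\| <= eps are treated as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windowing import DreamChart

__all__ = ["Segment", "Segmentation", "segment_chart", "DEFAULT_EPS"]

#: tolerance absorbing floating-point noise around the zero midline
DEFAULT_EPS = 1e-12


@dataclass(frozen=True)
class Segment:
    """One peak or trough: its boundaries, member points and signed area.

    ``points`` are ordered (x, y) pairs including any zero-valued boundary
    points (real chart zeros or interpolated crossings); ``auc`` is the
    trapezoid-rule area, positive for peaks and negative for troughs.
    """

    kind: str  # "peak" | "trough"
    start_x: float
    end_x: float
    points: np.ndarray  # shape (m, 2)
    auc: float

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "trough"):
            raise ValueError("segment kind must be 'peak' or 'trough'")
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.end_x < self.start_x:
            raise ValueError("end_x must be >= start_x")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Segmentation:
    """All peaks and troughs of one chart, in chronological order."""

    report_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def peaks(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "peak")

    @property
    def troughs(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "trough")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_troughs(self) -> int:
        return len(self.troughs)

    def to_frame(self) -> pd.DataFrame:
        """Segment table with columns report_id, kind, start_x, end_x, n_points, auc."""
        return pd.DataFrame(
            [
                {
                    "report_id": self.report_id,
                    "kind": s.kind,
                    "start_x": s.start_x,
                    "end_x": s.end_x,
                    "n_points": s.n_points,
                    "auc": s.auc,
                }
                for s in self.segments
            ],
            columns=["report_id", "kind", "start_x", "end_x", "n_points", "auc"],
        )


def _zero_crossing(x0: float, y0: float, x1: float, y1: float) -> float:
    """x-coordinate where the line through (x0, y0), (x1, y1) crosses zero."""
    return x0 + y0 * (x1 - x0) / (y0 - y1)


def _trapezoid(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def segment_chart(chart: DreamChart, eps: float = DEFAULT_EPS) -> Segmentation:
    """Demarcate the peaks and troughs of a dream chart.

    Maximal runs of y > eps form peaks and maximal runs of y < -eps form
    troughs; each segment's points include its interior chart points plus
    zero boundary points (existing zeros, interpolated sign-flip crossings,
    or nothing at a chart edge).  Segments are returned in chronological
    order and each nonzero chart point belongs to exactly one segment.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    x, y = chart.x, chart.y
    n = chart.n_windows
    signs = np.zeros(n, dtype=int)
    signs[y > eps] = 1
    signs[y < -eps] = -1

    segments: list[Segment] = []
    i = 0
    while i < n:
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == s:
            j += 1

        pts: list[tuple[float, float]] = []
        if i > 0:
            if signs[i - 1] == 0:
                pts.append((x[i - 1], 0.0))
            else:  # direct sign flip: interpolated crossing
                pts.append((_zero_crossing(x[i - 1], y[i - 1], x[i], y[i]), 0.0))
        pts.extend(zip(x[i : j + 1], y[i : j + 1]))
        if j < n - 1:
            if signs[j + 1] == 0:
                pts.append((x[j + 1], 0.0))
            else:
                pts.append((_zero_crossing(x[j], y[j], x[j + 1], y[j + 1]), 0.0))

        points = np.array(pts, dtype=float)
        segments.append(
            Segment(
                kind="peak" if s > 0 else "trough",
                start_x=float(points[0, 0]),
                end_x=float(points[-1, 0]),
                points=points,
                auc=_trapezoid(points),
            )
        )
        i = j + 1

    return Segmentation(report_id=chart.report_id, segments=tuple(segments))
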