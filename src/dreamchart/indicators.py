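"""The six per-dream emotion indicators.

Micro-level indicators come from the chart's peaks and troughs: the total
counts, and the intensity composites built from trapezoid-rule approximated
areas under the curve (aAUC).  Positive Emotion Intensity (PEI) is the sum
of peak aAUCs, Negative Emotion Intensity (NEI) the sum of trough aAUCs
(so NEI <= 0; larger negative values mean more negative emotion), and
Overall Emotion Intensity is OEI = PEI + |NEI| — trough areas enter in
absolute value so that negative emotion adds to, rather than subtracts
from, the total emotional intensity.  The macro-level emotion gradient is
supplied by the trendline fit (see :mod:`dreamchart.trend`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .segmentation import Segment, Segmentation
from .windowing import DreamChart

__all__ = [
    "EmotionIndicators",
    "trapezoid_auc",
    "positive_emotion_intensity",
    "negative_emotion_intensity",
    "overall_emotion_intensity",
    "compute_indicators",
    "INDICATOR_COLUMNS",
]

INDICATOR_COLUMNS = (
    "total_peaks",
    "total_troughs",
    "pei",
    "nei",
    "oei",
    "emotion_gradient",
)


@dataclass(frozen=True)
class EmotionIndicators:
    """The six emotion-indicator scalars for one dream report."""

    report_id: str
    total_peaks: int
    total_troughs: int
    pei: float
    nei: float
    oei: float
    emotion_gradient: float

    def __post_init__(self) -> None:
        if self.pei < 0:
            raise ValueError("pei must be >= 0")
        if self.nei > 0:
            raise ValueError("nei must be <= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def trapezoid_auc(segment: Segment | np.ndarray) -> float:
    """Signed area of one segment by the trapezoid rule.

    The area is the sum over consecutive point pairs of
    (x_{i+1} - x_i) * (y_i + y_{i+1}) / 2 — positive for peaks, negative for
    troughs.  Zero boundary points are included as endpoints, which makes
    single-interior-point segments well defined; a degenerate segment with
    fewer than two points has zero area.
    """
    points = segment.points if isinstance(segment, Segment) else np.asarray(segment, float)
    if len(points) < 2:
        return 0.0
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def positive_emotion_intensity(segmentation: Segmentation) -> float:
    """PEI: sum of the approximated AUCs of all peaks (0 when there are none)."""
    return float(sum(trapezoid_auc(s) for s in segmentation.peaks))


def negative_emotion_intensity(segmentation: Segmentation) -> float:
    """NEI: sum of the approximated AUCs of all troughs (0 when there are none).

    Always <= 0; larger negative values denote higher negative emotion
    intensity.
    """
    return float(sum(trapezoid_auc(s) for s in segmentation.troughs))


def overall_emotion_intensity(pei: float, nei: float) -> float:
    """OEI = PEI + |NEI|."""
    if pei < 0:
        raise ValueError("pei must be >= 0")
    if nei > 0:
        raise ValueError("nei must be <= 0")
    return pei + abs(nei)


def compute_indicators(
    chart: DreamChart,
    segmentation: Segmentation,
    emotion_gradient: float = 0.0,
) -> EmotionIndicators:
    """Assemble the six indicators for one chart.

    The emotion gradient comes from the trendline fit and is passed through;
    the other five are derived from the segmentation.
    """
    pei = positive_emotion_intensity(segmentation)
    nei = negative_emotion_intensity(segmentation)
    # clip away the one-ULP negatives a sum of positive trapezoids can produce
    pei = max(pei, 0.0)
    nei = min(nei, 0.0)
    return EmotionIndicators(
        report_id=chart.report_id,
        total_peaks=segmentation.n_peaks,
        total_troughs=segmentation.n_troughs,
        pei=pei,
        nei=nei,
        oei=overall_emotion_intensity(pei, nei),
        emotion_gradient=emotion_gradient,
    )
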