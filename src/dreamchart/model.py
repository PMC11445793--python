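"""Model/Results surface over the dream-emotion pipeline.

:class:`DreamEmotionModel` is built from a batch of dream reports and a
sentiment lexicon; ``fit()`` runs the full pipeline (scoring -> sliding
window -> segmentation -> trapezoid intensities -> trendline) and returns a
:class:`DreamEmotionResults` carrying the per-report artifacts, the
indicator table, a ``summary()``, plotting, CSV export, and
``correlate(externals)`` for the validation layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .lexicon import SentimentLexicon
from .scoring import DreamReport, ValenceSeries, EmptyReportError, score_report, MODES
from .windowing import WindowConfig, DreamChart, make_chart, NORMALIZERS
from .segmentation import Segmentation, segment_chart, DEFAULT_EPS
from .indicators import EmotionIndicators, compute_indicators, INDICATOR_COLUMNS
from .trend import TrendFit, fit_trend
from .stats import correlation_matrix, TIE_POLICIES, ADJUSTMENTS

__all__ = [
    "PipelineConfig",
    "ReportAnalysis",
    "DreamEmotionModel",
    "DreamEmotionResults",
    "CorrelationAnalysis",
    "analyze_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, validated and serializable.

    scoring_mode   : 'lexicon_only' (default) or 'vader_heuristics'
    window_length  : tokens per sliding window (default 30)
    overlap        : tokens shared by consecutive windows (default 29)
    normalizer     : window-sum divisor ('n_windows' default)
    trend_degree   : polynomial trendline degree (default 2)
    r2_floor       : minimum r-squared for trend eligibility (default 0)
    eps            : zero tolerance for segmentation (default 1e-12)
    alpha          : significance level for the correlation edge list
    tie_policy     : tie detection in 'either' (default) or 'both' vectors
    adjust         : multiple-testing adjustment (None | 'holm' | 'bh')
    """

    scoring_mode: str = "lexicon_only"
    window_length: int = 30
    overlap: int = 29
    normalizer: str = "n_windows"
    trend_degree: int = 2
    r2_floor: float = 0.0
    eps: float = DEFAULT_EPS
    alpha: float = 0.05
    tie_policy: str = "either"
    adjust: str | None = None

    def __post_init__(self) -> None:
        if self.scoring_mode not in MODES:
            raise ValueError(f"scoring_mode must be one of {MODES}")
        if self.normalizer not in NORMALIZERS:
            raise ValueError(f"normalizer must be one of {NORMALIZERS}")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
        if self.adjust not in ADJUSTMENTS:
            raise ValueError(f"adjust must be one of {ADJUSTMENTS}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        WindowConfig(self.window_length, self.overlap, self.normalizer)  # validate

    @property
    def window(self) -> WindowConfig:
        return WindowConfig(self.window_length, self.overlap, self.normalizer)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ReportAnalysis:
    """All per-report pipeline artifacts for one dream."""

    report: DreamReport
    series: ValenceSeries
    chart: DreamChart
    segmentation: Segmentation
    trend: TrendFit
    indicators: EmotionIndicators


def analyze_report(
    report: DreamReport,
    lexicon: SentimentLexicon,
    config: PipelineConfig | None = None,
) -> ReportAnalysis:
    """Run the full single-report pipeline."""
    config = config or PipelineConfig()
    series = score_report(report, lexicon, mode=config.scoring_mode)
    chart = make_chart(series, config.window)
    segmentation = segment_chart(chart, eps=config.eps)
    trend = fit_trend(chart, degree=config.trend_degree, r2_floor=config.r2_floor)
    indicators = compute_indicators(chart, segmentation, trend.emotion_gradient)
    return ReportAnalysis(report, series, chart, segmentation, trend, indicators)


class DreamEmotionModel:
    """Sequential-emotion model of a batch of dream reports.

    Parameters
    ----------
    reports
        The pre-cleaned dream descriptions to analyze.
    lexicon
        Sentiment lexicon supplying per-word valences.
    config
        Pipeline tunables; defaults follow the standard protocol
        (30-word windows overlapping by 29, window sums divided by the
        report's window count, degree-2 trendline).
    """

    def __init__(
        self,
        reports: Sequence[DreamReport],
        lexicon: SentimentLexicon,
        config: PipelineConfig | None = None,
    ) -> None:
        reports = list(reports)
        if not reports:
            raise ValueError("need at least one report")
        ids = [r.report_id for r in reports]
        if len(set(ids)) != len(ids):
            raise ValueError("report_ids must be unique within a batch")
        self.reports = reports
        self.lexicon = lexicon
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        lexicon: SentimentLexicon,
        config: PipelineConfig | None = None,
        id_col: str = "id",
        text_col: str = "text",
    ) -> "DreamEmotionModel":
        """Build a model from a DataFrame with id and text columns."""
        reports = [
            DreamReport(report_id=str(row[id_col]), text=str(row[text_col]))
            for _, row in frame.iterrows()
        ]
        return cls(reports, lexicon, config)

    def fit(self) -> "DreamEmotionResults":
        """Run the pipeline on every report.

        Reports that cannot be scored (no tokens, e.g. digits-only text)
        are skipped with a warning and listed in ``results.skipped``.
        """
        analyses: dict[str, ReportAnalysis] = {}
        skipped: list[tuple[str, str]] = []
        for report in self.reports:
            try:
                analyses[report.report_id] = analyze_report(report, self.lexicon, self.config)
            except EmptyReportError as err:
                warnings.warn(f"skipping report {report.report_id!r}: {err}", stacklevel=2)
                skipped.append((report.report_id, str(err)))
        if not analyses:
            raise ValueError("no report produced a usable valence series")
        return DreamEmotionResults(self, analyses, skipped)


class DreamEmotionResults:
    """Fitted per-report artifacts and the cohort indicator table."""

    def __init__(
        self,
        model: DreamEmotionModel,
        analyses: dict[str, ReportAnalysis],
        skipped: list[tuple[str, str]],
    ) -> None:
        self.model = model
        self.analyses = analyses
        self.skipped = skipped

    def __getitem__(self, report_id: str) -> ReportAnalysis:
        return self.analyses[report_id]

    @property
    def report_ids(self) -> list[str]:
        return list(self.analyses)

    @property
    def indicators(self) -> pd.DataFrame:
        """One row per report: the six emotion indicators."""
        return pd.DataFrame(
            [a.indicators.as_dict() for a in self.analyses.values()],
            columns=["report_id", *INDICATOR_COLUMNS],
        )

    @property
    def word_counts(self) -> pd.Series:
        return pd.Series(
            {rid: a.series.word_count for rid, a in self.analyses.items()}, name="word_count"
        )

    def charts_frame(self) -> pd.DataFrame:
        """All charts stacked in tidy form (report_id, x, y)."""
        return pd.concat([a.chart.to_frame() for a in self.analyses.values()], ignore_index=True)

    def segments_frame(self) -> pd.DataFrame:
        frames = [a.segmentation.to_frame() for a in self.analyses.values()]
        return pd.concat(frames, ignore_index=True)

    def trend_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.analyses.values():
            t = a.trend
            row = {"report_id": t.report_id, "degree": t.degree}
            row.update({f"c{i}": c for i, c in enumerate(t.coefficients)})
            row.update(
                {
                    "r_squared": t.r_squared,
                    "emotion_gradient": t.emotion_gradient,
                    "linear_slope": t.linear_slope,
                    "eligible": t.eligible,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def correlate(self, externals: pd.DataFrame) -> "CorrelationAnalysis":
        """Correlate the six indicators against an external-variables table.

        ``externals`` must carry a ``report_id`` column (or index) matching
        the fitted reports; all other columns are treated as numeric
        external variables.
        """
        cfg = self.model.config
        results, edges = correlation_matrix(
            self.indicators,
            externals,
            alpha=cfg.alpha,
            tie_policy=cfg.tie_policy,
            adjust=cfg.adjust,
        )
        return CorrelationAnalysis(results, edges, alpha=cfg.alpha)

    def plot_chart(self, report_id: str, **kwargs):
        """Dream chart of one report with shaded peaks/troughs (see
        :func:`dreamchart.plotting.plot_chart`)."""
        from .plotting import plot_chart

        a = self.analyses[report_id]
        return plot_chart(a.chart, a.segmentation, a.trend, **kwargs)

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write indicator, chart, segment and trend tables plus the config
        echo to ``outdir``; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "indicators": outdir / "indicators.csv",
            "charts": outdir / "charts.csv",
            "segments": outdir / "segments.csv",
            "trends": outdir / "trends.csv",
            "config": outdir / "config.json",
        }
        self.indicators.to_csv(paths["indicators"], index=False)
        self.charts_frame().to_csv(paths["charts"], index=False)
        self.segments_frame().to_csv(paths["segments"], index=False)
        self.trend_frame().to_csv(paths["trends"], index=False)
        paths["config"].write_text(self.model.config.to_json())
        if self.skipped:
            skip_path = outdir / "skipped.csv"
            pd.DataFrame(self.skipped, columns=["report_id", "reason"]).to_csv(
                skip_path, index=False
            )
            paths["skipped"] = skip_path
        return paths

    def summary(self) -> str:
        """Readable cohort summary: per-report indicators and descriptives."""
        ind = self.indicators.set_index("report_id")
        desc = ind.agg(["mean", "std", "min", "max"]).T
        lines = [
            "Dream emotion indicators",
            "=" * 72,
            f"reports analyzed: {len(self.analyses)}"
            + (f"  (skipped: {len(self.skipped)})" if self.skipped else ""),
            f"mean word count: {self.word_counts.mean():.3f}"
            f"  (range {self.word_counts.min()}-{self.word_counts.max()})",
            "",
            ind.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "descriptives",
            "-" * 72,
            desc.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


@dataclass
class CorrelationAnalysis:
    """Correlation-layer output: the long-format result table and the
    significant signed edge list."""

    results: pd.DataFrame
    edges: pd.DataFrame
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            "Indicator x external-variable correlations",
            "=" * 72,
            f"pairs tested: {len(self.results)}   alpha = {self.alpha} (uncorrected)"
            if "p_adjusted" not in self.results
            else f"pairs tested: {len(self.results)}   alpha = {self.alpha} (adjusted)",
            "",
            self.results.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "",
            f"significant edges: {len(self.edges)}",
        ]
        if len(self.edges):
            lines.append(self.edges.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
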