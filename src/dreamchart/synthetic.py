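"""Synthetic dream reports with planted emotional structure.

Real dream-report corpora are rarely shareable, so every pipeline stage is
tested against generated reports whose ground truth is known exactly.  A
report is built from an :class:`EmotionScript` — an ordered plan of
positive, negative, and neutral token runs with chosen amplitudes —
realized from a toy lexicon of synthetic tokens (``pos3_a40``,
``neg0_a65``, fillers) whose valences are constructed, so fixture
correctness never depends on the contents of any real sentiment lexicon.

Ground truth for each report contains the exact pre-window valence series
plus the windowed chart and peak/trough counts computed by the module's
independent brute-force oracles (:func:`oracle_windowed_series`,
:func:`oracle_peak_trough_counts`), deliberately naive re-implementations
kept separate from the production code paths.

:func:`generate_cohort` additionally fabricates an external-variables table
as linear functions of the true indicators plus Gaussian noise, so expected
correlation signs are known; default word counts are drawn uniformly from
46-202, the word-count range typical of morning dream reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import SentimentLexicon
from .scoring import DreamReport

__all__ = [
    "Run",
    "EmotionScript",
    "toy_lexicon",
    "generate_report",
    "generate_cohort",
    "sample_script",
    "ExternalSpec",
    "oracle_windowed_series",
    "oracle_peak_trough_counts",
    "oracle_intensities",
]

#: toy lexicon amplitude granularity: normalized valences are multiples of this
AMPLITUDE_STEP = 0.05
_N_VARIANTS = 5  # token spellings per (sign, amplitude) level
_N_FILLERS = 60  # neutral tokens (absent from the lexicon, so valence 0)

#: word-count range of the emulated corpus of morning dream reports
WORD_COUNT_RANGE = (46, 202)
DEFAULT_N_REPORTS = 14


@dataclass(frozen=True)
class Run:
    """One scripted run of tokens: ``kind`` in {positive, negative, neutral},
    ``length`` tokens, normalized valence ``amplitude`` in [0, 1]
    (ignored for neutral runs)."""

    kind: str
    length: int
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("positive", "negative", "neutral"):
            raise ValueError("run kind must be positive|negative|neutral")
        if self.length < 1:
            raise ValueError("run length must be >= 1")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in [0, 1]")


@dataclass(frozen=True)
class EmotionScript:
    """An ordered plan of token runs realizing one synthetic dream report."""

    plan: tuple[Run, ...]
    seed: int = 0
    report_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan", tuple(self.plan))
        if not self.plan:
            raise ValueError("script plan must contain at least one run")

    @property
    def length(self) -> int:
        return sum(r.length for r in self.plan)


def toy_lexicon() -> SentimentLexicon:
    """A constructed lexicon of synthetic tokens with exactly known valences.

    Tokens are pure letters so they survive tokenization intact:
    ``pos{v}amp{s}`` / ``neg{v}amp{s}`` carry normalized valence
    ±(step of 0.05) for amplitude letters s = 'a' (0.05) ... 't' (1.00) and
    spelling variants v in 'a'-'e'.  Neutral filler tokens are deliberately
    absent from the lexicon (lookup yields 0).
    """
    scale_max = 4.0
    entries: dict[str, float] = {}
    for step in range(1, int(round(1 / AMPLITUDE_STEP)) + 1):
        amp = step * AMPLITUDE_STEP
        amp_letter = chr(ord("a") + step - 1)
        for v in range(_N_VARIANTS):
            variant = chr(ord("a") + v)
            entries[f"pos{variant}amp{amp_letter}"] = amp * scale_max
            entries[f"neg{variant}amp{amp_letter}"] = -amp * scale_max
    return SentimentLexicon(entries=entries, scale_max=scale_max, name="toy")


def _amplitude_letter(amplitude: float) -> str:
    steps = amplitude / AMPLITUDE_STEP
    if abs(steps - round(steps)) > 1e-9 or not (0 < amplitude <= 1.0):
        raise ValueError(
            f"amplitude {amplitude} not achievable by the toy lexicon "
            f"(multiples of {AMPLITUDE_STEP} in (0, 1])"
        )
    return chr(ord("a") + int(round(steps)) - 1)


def generate_report(
    script: EmotionScript, lexicon: SentimentLexicon | None = None
) -> tuple[DreamReport, dict]:
    """Realize a script as a synthetic dream report plus its ground truth.

    Returns ``(report, truth)`` where ``truth`` holds the exact pre-window
    valence ``values``, the ``tokens``, and — for the default 30-word /
    29-overlap windowing — the oracle chart ``chart_y`` and the expected
    ``n_peaks`` / ``n_troughs`` from the brute-force oracles.  Identical
    scripts (including seed) give byte-identical reports.
    """
    lexicon = lexicon or toy_lexicon()
    rng = np.random.default_rng(script.seed)
    tokens: list[str] = []
    values: list[float] = []
    for run in script.plan:
        if run.kind == "neutral":
            for _ in range(run.length):
                idx = int(rng.integers(_N_FILLERS))
                tokens.append("filler" + chr(ord("a") + idx // 26) + chr(ord("a") + idx % 26))
                values.append(0.0)
        else:
            amp_letter = _amplitude_letter(run.amplitude)
            prefix = "pos" if run.kind == "positive" else "neg"
            sign = 1.0 if run.kind == "positive" else -1.0
            for _ in range(run.length):
                variant = chr(ord("a") + int(rng.integers(_N_VARIANTS)))
                name = f"{prefix}{variant}amp{amp_letter}"
                if name not in lexicon:
                    raise ValueError(f"token {name} missing from lexicon")
                tokens.append(name)
                values.append(sign * run.amplitude)

    report = DreamReport(report_id=script.report_id, text=" ".join(tokens))
    exact = np.array(values)
    chart_y = oracle_windowed_series(exact)
    n_peaks, n_troughs = oracle_peak_trough_counts(chart_y)
    truth = {
        "tokens": tokens,
        "values": exact,
        "chart_y": chart_y,
        "n_peaks": n_peaks,
        "n_troughs": n_troughs,
    }
    return report, truth


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the production windowing/segmentation)
# ---------------------------------------------------------------------------


def oracle_windowed_series(
    values: np.ndarray, window_length: int = 30, divide_by_count: bool = True
) -> np.ndarray:
    """Reference sliding-window standardization by an explicit double loop.

    Kept deliberately naive and separate from
    :func:`dreamchart.windowing.make_chart` so the two can check each other.
    """
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L < window_length:
        sums = [sum(float(v) for v in values)]
    else:
        sums = []
        for start in range(L - window_length + 1):
            total = 0.0
            for k in range(start, start + window_length):
                total += float(values[k])
            sums.append(total)
    W = len(sums)
    divisor = W if divide_by_count else 1
    return np.array([s / divisor for s in sums])


def oracle_intensities(y: np.ndarray, eps: float = 1e-12) -> tuple[float, float]:
    """Reference (PEI, NEI) by clip-and-integrate rather than segment-and-sum.

    Inserts the linearly interpolated zero crossing between consecutive
    opposite-sign points, then integrates the positive and negative parts of
    the piecewise-linear interpolant by the trapezoid rule over the
    augmented grid.  Algebraically equivalent to summing per-segment areas,
    but computed by a different route.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 2:
        return 0.0, 0.0
    ax = [x[0]]
    ay = [y[0]]
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 > eps and y1 < -eps) or (y0 < -eps and y1 > eps):
            xc = x[i] + y0 * (x[i + 1] - x[i]) / (y0 - y1)
            ax.append(xc)
            ay.append(0.0)
        ax.append(x[i + 1])
        ay.append(y[i + 1])
    ax_arr = np.array(ax)
    ay_arr = np.array(ay)
    pos = np.where(ay_arr > eps, ay_arr, 0.0)
    neg = np.where(ay_arr < -eps, ay_arr, 0.0)
    pei = float(np.trapezoid(pos, ax_arr))
    nei = float(np.trapezoid(neg, ax_arr))
    return max(pei, 0.0), min(nei, 0.0)


def oracle_peak_trough_counts(y: np.ndarray, eps: float = 1e-12) -> tuple[int, int]:
    """Reference peak/trough counter: a run-length scan over the sign pattern."""
    peaks = troughs = 0
    prev = 0
    for value in np.asarray(y, dtype=float):
        sign = 1 if value > eps else (-1 if value < -eps else 0)
        if sign == 1 and prev != 1:
            peaks += 1
        elif sign == -1 and prev != -1:
            troughs += 1
        prev = sign
    return peaks, troughs


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExternalSpec:
    """One fabricated external variable: ``value = intercept + slope *
    indicator + Normal(0, sigma)`` per report."""

    indicator: str
    slope: float = 1.0
    intercept: float = 0.0
    sigma: float = 0.0


def sample_script(
    rng: np.random.Generator,
    report_id: str,
    word_count: int | None = None,
) -> EmotionScript:
    """Draw a random script emulating a morning dream report.

    Word count is uniform on 46-202 unless given; emotional runs of 5-20
    tokens at amplitudes 0.30-1.00 alternate with neutral runs of 8-35
    tokens, mimicking the interleaving of emotional episodes and neutral
    narration.
    """
    if word_count is None:
        word_count = int(rng.integers(WORD_COUNT_RANGE[0], WORD_COUNT_RANGE[1] + 1))
    plan: list[Run] = []
    remaining = word_count
    emotional_next = bool(rng.integers(2))
    while remaining > 0:
        if emotional_next:
            length = int(min(remaining, rng.integers(5, 21)))
            amp_steps = int(rng.integers(6, 21))  # 0.30 ... 1.00
            plan.append(
                Run(
                    kind="positive" if rng.integers(2) else "negative",
                    length=length,
                    amplitude=amp_steps * AMPLITUDE_STEP,
                )
            )
        else:
            length = int(min(remaining, rng.integers(8, 36)))
            plan.append(Run(kind="neutral", length=length))
        remaining -= length
        emotional_next = not emotional_next
    return EmotionScript(
        plan=tuple(plan),
        seed=int(rng.integers(2**31)),
        report_id=report_id,
    )


def generate_cohort(
    n_reports: int = DEFAULT_N_REPORTS,
    script_sampler=None,
    externals_model: dict[str, ExternalSpec] | None = None,
    seed: int = 0,
) -> tuple[list[DreamReport], pd.DataFrame, dict]:
    """Generate a cohort of synthetic reports plus an external-variables table.

    ``script_sampler(rng, report_id)`` may override the default report
    sampler.  ``externals_model`` maps variable name -> :class:`ExternalSpec`;
    each variable is built from the cohort's *true* indicator values (from
    the ground-truth oracle pipeline) plus Gaussian noise, so the expected
    correlation sign of every (indicator, variable) edge is known.  Returns
    ``(reports, externals, truth)`` with ``truth['reports']`` holding each
    report's per-report ground truth and ``truth['indicators']`` the oracle
    indicator table.
    """
    if n_reports < 3:
        raise ValueError("a cohort needs at least 3 reports")
    rng = np.random.default_rng(seed)
    sampler = script_sampler or sample_script

    reports: list[DreamReport] = []
    per_report: dict[str, dict] = {}
    rows = []
    for i in range(n_reports):
        rid = f"dream_{i + 1:02d}"
        script = sampler(rng, rid)
        report, truth = generate_report(script)
        truth["script"] = script
        reports.append(report)
        per_report[rid] = truth

        y = truth["chart_y"]
        n_peaks, n_troughs = truth["n_peaks"], truth["n_troughs"]
        pei, nei = oracle_intensities(y)
        rows.append(
            {
                "report_id": rid,
                "total_peaks": n_peaks,
                "total_troughs": n_troughs,
                "pei": pei,
                "nei": nei,
                "oei": pei + abs(nei),
            }
        )
    indicators = pd.DataFrame(rows).set_index("report_id")

    if externals_model is None:
        externals_model = {
            "rem_pct": ExternalSpec("oei", slope=5.0, intercept=20.0, sigma=1.0),
            "awakenings": ExternalSpec("total_troughs", slope=1.5, intercept=2.0, sigma=0.5),
        }
    ext = pd.DataFrame(index=indicators.index)
    for name, spec in externals_model.items():
        if spec.indicator not in indicators.columns:
            raise ValueError(f"externals_model references unknown indicator {spec.indicator!r}")
        base = indicators[spec.indicator].to_numpy(dtype=float)
        if spec.sigma == 0.0 and (spec.slope == 0.0 or np.ptp(base) == 0.0):
            raise ValueError(f"external variable {name!r} is degenerate (zero variance)")
        noise = rng.normal(0.0, spec.sigma, size=n_reports) if spec.sigma > 0 else 0.0
        ext[name] = spec.intercept + spec.slope * base + noise
    ext = ext.reset_index()

    truth = {"reports": per_report, "indicators": indicators.reset_index(), "seed": seed}
    return reports, ext, truth
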