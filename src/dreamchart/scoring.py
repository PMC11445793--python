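"""Word-for-word valence scoring of dream reports.

Tokenizes a report and assigns each token a continuous valence rating from a
sentiment lexicon, yielding the ordered valence series the rest of the
pipeline consumes.  Negative values encode negative emotion, zero is neutral,
positive values encode positive emotion; all values are normalized to
[-1, +1] by the lexicon's scale maximum.

Two scoring modes are available:

``lexicon_only``
    Pure per-token lookup.  Deterministic and context-free: each value
    depends on its own token alone.

``vader_heuristics``
    Additionally applies the word-level negation and booster modifiers of
    the VADER sentiment algorithm within a trailing three-token context
    window: a preceding negation flips and damps the valence by a factor of
    -0.74, and preceding intensity modifiers add or subtract 0.293 (damped
    by distance) before normalization.  Capitalization and punctuation
    emphasis heuristics, which operate at sentence level, are not applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .lexicon import SentimentLexicon

__all__ = ["DreamReport", "ValenceSeries", "tokenize", "score_tokens", "EmptyReportError"]

#: valence sign-flip factor applied by a preceding negation (VADER's N_SCALAR)
NEGATION_SCALAR = -0.74
#: valence increment contributed by an intensity booster (VADER's B_INCR)
BOOSTER_INCREMENT = 0.293
#: distance damping for modifiers 2 and 3 tokens back
_DISTANCE_DAMPING = {1: 1.0, 2: 0.95, 3: 0.9}

NEGATIONS = frozenset(
    """not no never none nobody nothing neither nor cannot can't won't don't
    doesn't didn't isn't aren't wasn't weren't hasn't haven't hadn't
    shouldn't wouldn't couldn't mustn't ain't without hardly scarcely
    rarely""".split()
)

BOOSTERS = {
    "absolutely": BOOSTER_INCREMENT,
    "amazingly": BOOSTER_INCREMENT,
    "completely": BOOSTER_INCREMENT,
    "considerably": BOOSTER_INCREMENT,
    "deeply": BOOSTER_INCREMENT,
    "enormously": BOOSTER_INCREMENT,
    "entirely": BOOSTER_INCREMENT,
    "especially": BOOSTER_INCREMENT,
    "exceptionally": BOOSTER_INCREMENT,
    "extremely": BOOSTER_INCREMENT,
    "hugely": BOOSTER_INCREMENT,
    "incredibly": BOOSTER_INCREMENT,
    "intensely": BOOSTER_INCREMENT,
    "really": BOOSTER_INCREMENT,
    "remarkably": BOOSTER_INCREMENT,
    "so": BOOSTER_INCREMENT,
    "thoroughly": BOOSTER_INCREMENT,
    "totally": BOOSTER_INCREMENT,
    "tremendously": BOOSTER_INCREMENT,
    "utterly": BOOSTER_INCREMENT,
    "very": BOOSTER_INCREMENT,
    "almost": -BOOSTER_INCREMENT,
    "barely": -BOOSTER_INCREMENT,
    "kinda": -BOOSTER_INCREMENT,
    "marginally": -BOOSTER_INCREMENT,
    "mildly": -BOOSTER_INCREMENT,
    "partly": -BOOSTER_INCREMENT,
    "slightly": -BOOSTER_INCREMENT,
    "somewhat": -BOOSTER_INCREMENT,
    "sorta": -BOOSTER_INCREMENT,
}

MODES = ("lexicon_only", "vader_heuristics")

# maximal runs of letters/apostrophes; digits and standalone punctuation dropped
_TOKEN_RE = re.compile(r"(?:[^\W\d_]|')+", re.UNICODE)


class EmptyReportError(ValueError):
    """Raised when a report contains no scoreable tokens."""


@dataclass(frozen=True)
class DreamReport:
    """One pre-cleaned dream description (the dream experience itself,
    with any waking commentary already removed)."""

    report_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise EmptyReportError(f"report {self.report_id!r}: empty text")


@dataclass(frozen=True)
class ValenceSeries:
    """Per-token continuous valence ratings for one report, in report order.

    ``values`` lie in [-1, +1]: negative = negative emotion, 0 = neutral,
    positive = positive emotion.
    """

    report_id: str
    tokens: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) != len(values):
            raise ValueError("tokens and values must have equal length")
        if len(values) == 0:
            raise ValueError("a valence series must contain at least one token")
        if not np.all(np.isfinite(values)):
            raise ValueError("valence values must be finite")
        if np.any(np.abs(values) > 1.0 + 1e-12):
            raise ValueError("valence values must lie in [-1, +1]")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def word_count(self) -> int:
        return len(self.tokens)


def tokenize(report: DreamReport | str) -> list[str]:
    """Split a report into lowercase word tokens.

    Tokens are maximal runs of letters and apostrophes; digits and standalone
    punctuation are dropped, internal apostrophes (``don't``) are retained,
    and enclosing quote-apostrophes are stripped.  The length of the result
    is the report's word count.

    Raises
    ------
    EmptyReportError
        If no tokens remain.
    """
    text = report.text if isinstance(report, DreamReport) else report
    raw = _TOKEN_RE.findall(text.lower())
    tokens = [t.strip("'") for t in raw]
    tokens = [t for t in tokens if t]
    if not tokens:
        rid = report.report_id if isinstance(report, DreamReport) else "<text>"
        raise EmptyReportError(f"report {rid!r}: no tokens after tokenization")
    return tokens


def score_tokens(
    tokens: list[str] | tuple[str, ...],
    lexicon: SentimentLexicon,
    mode: str = "lexicon_only",
    report_id: str = "",
) -> ValenceSeries:
    """Assign each token a valence rating in [-1, +1].

    In ``lexicon_only`` mode each value is the token's lexicon mean valence
    divided by ``lexicon.scale_max`` (0 when absent).  In
    ``vader_heuristics`` mode, preceding negations and boosters within three
    tokens modify the raw valence before normalization; outputs are clamped
    to [-1, +1].
    """
    if mode not in MODES:
        raise ValueError(f"unknown scoring mode {mode!r}; expected one of {MODES}")
    if len(tokens) == 0:
        raise EmptyReportError("cannot score an empty token list")

    raw = np.array([lexicon.valence(t) for t in tokens], dtype=float)

    if mode == "vader_heuristics":
        for i, v in enumerate(raw):
            if v == 0.0:
                continue
            negated = False
            for dist in (1, 2, 3):
                j = i - dist
                if j < 0:
                    break
                prev = tokens[j]
                if prev in BOOSTERS and lexicon.valence(prev) == 0.0:
                    v += np.sign(v) * BOOSTERS[prev] * _DISTANCE_DAMPING[dist]
                if prev in NEGATIONS:
                    negated = True
            if negated:
                v *= NEGATION_SCALAR
            raw[i] = v

    values = np.clip(raw / lexicon.scale_max, -1.0, 1.0)
    return ValenceSeries(report_id=report_id, tokens=tuple(tokens), values=values)


def score_report(
    report: DreamReport, lexicon: SentimentLexicon, mode: str = "lexicon_only"
) -> ValenceSeries:
    """Tokenize and score a report in one call."""
    return score_tokens(tokenize(report), lexicon, mode=mode, report_id=report.report_id)
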