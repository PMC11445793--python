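"""Sentiment lexicon: token -> mean valence lookup.

A lexicon maps lowercase tokens to continuous valence ratings on a native
scale (for VADER-format lexicons, -4 ... +4).  Lookup of an absent token is
neutral (0).  Downstream code normalizes ratings to [-1, +1] by dividing by
``scale_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping


@dataclass(frozen=True)
class SentimentLexicon:
    """Mapping from lowercase token to mean valence on the lexicon's native scale.

    Parameters
    ----------
    entries
        Token -> mean valence.  Keys must be lowercase; absolute values must
        not exceed ``scale_max``.
    scale_max
        Positive number used to normalize ratings to [-1, +1].  4.0 for
        VADER-format lexicons.
    """

    entries: Mapping[str, float]
    scale_max: float = 4.0
    name: str = field(default="lexicon", compare=False)

    def __post_init__(self) -> None:
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")
        for token, valence in self.entries.items():
            if token != token.lower():
                raise ValueError(f"lexicon token not lowercase: {token!r}")
            if abs(valence) > self.scale_max:
                raise ValueError(
                    f"|valence| of {token!r} ({valence}) exceeds scale_max {self.scale_max}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def valence(self, token: str) -> float:
        """Raw (native-scale) valence of ``token``; 0.0 when absent."""
        return self.entries.get(token, 0.0)

    def normalized(self, token: str) -> float:
        """Valence of ``token`` normalized to [-1, +1]."""
        return self.entries.get(token, 0.0) / self.scale_max


def load_lexicon(path: str | Path, scale_max: float = 4.0) -> SentimentLexicon:
    """Read a VADER-format lexicon file.

    Format: tab-separated ``token<TAB>mean<TAB>sd<TAB>[ratings...]``; only the
    first two columns are consumed.  Lines that are empty or lack a numeric
    second column are skipped.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            try:
                mean = float(parts[1])
            except ValueError:
                continue
            entries[parts[0].lower()] = mean
    return SentimentLexicon(entries=entries, scale_max=scale_max, name=path.stem)


def demo_lexicon() -> SentimentLexicon:
    """The small demonstration lexicon bundled with the package.

    A hand-written, synthetic stand-in for a full sentiment lexicon: a few
    hundred common English emotion words with plausible valences on the
    -4 ... +4 scale.  Suitable for demos and tests; for research use, supply
    a full VADER-format lexicon file via :func:`load_lexicon`.
    """
    ref = resources.files("dreamchart").joinpath("data/demo_lexicon_synthetic.tsv")
    with resources.as_file(ref) as path:
        lex = load_lexicon(path)
    return SentimentLexicon(entries=lex.entries, scale_max=4.0, name="demo")
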