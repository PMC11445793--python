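import numpy as np
import pytest

from dreamchart import DreamChart, ValenceSeries
from dreamchart.synthetic import toy_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return toy_lexicon()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def make_series(values, report_id="t", tokens=None):
    values = np.asarray(values, dtype=float)
    tokens = tokens or [f"tok{i}" for i in range(len(values))]
    return ValenceSeries(report_id=report_id, tokens=tuple(tokens), values=values)


def make_dream_chart(y, report_id="t"):
    y = np.asarray(y, dtype=float)
    return DreamChart(
        report_id=report_id,
        x=np.arange(1, len(y) + 1, dtype=float),
        y=y,
        n_windows=len(y),
        raw_length=len(y) + 29,
    )


@pytest.fixture()
def chart_factory():
    return make_dream_chart


@pytest.fixture()
def series_factory():
    return make_series
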