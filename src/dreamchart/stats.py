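"""Tie-aware correlation of emotion indicators with external variables.

The validation protocol correlates each emotion indicator with each
external sleep, state, or trait variable.  Because small samples of these
variables are typically non-normal, the rank-based Spearman's rho is used —
but only when the data contain no ties, since ties distort rank
correlations at small n.  When any value repeats, Pearson's r is used as
the fallback.  P-values are reported uncorrected by default (an optional
Holm or Benjamini-Hochberg adjustment is available); pairs with p below
alpha form a signed edge list for network-style summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "overnight_change",
    "correlate",
    "correlation_matrix",
]

TIE_POLICIES = ("either", "both")
ADJUSTMENTS = (None, "holm", "bh")


@dataclass(frozen=True)
class CorrelationResult:
    """One indicator x external-variable correlation."""

    x_name: str
    y_name: str
    coefficient: float
    method: str  # "spearman" | "pearson"
    p_value: float
    n: int
    ties_present: bool

    def as_dict(self) -> dict:
        return asdict(self)


def overnight_change(evening: float, morning: float) -> float:
    """Overnight percentage change in an affect score: 100 * (morning - evening) / evening.

    Positive values indicate an overnight increase.  Undefined (NaN) when
    the evening score is zero or missing.
    """
    if evening is None or morning is None:
        return float("nan")
    evening = float(evening)
    morning = float(morning)
    if not np.isfinite(evening) or not np.isfinite(morning) or evening == 0.0:
        return float("nan")
    return 100.0 * (morning - evening) / evening


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def correlate(
    x,
    y,
    tie_policy: str = "either",
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Correlate two paired vectors under the tie-fallback rule.

    Spearman's rho (t-approximation p-value) when the data are tie-free;
    Pearson's r when ties are present.  ``tie_policy`` decides whether a tie
    in *either* vector (default) or only ties in *both* vectors trigger the
    Pearson fallback.  Pairs with a missing value in either vector are
    dropped (listwise deletion); at least 3 complete pairs are required.
    A constant vector leaves the coefficient undefined (NaN, with a
    warning).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")

    tx, ty = _has_ties(x), _has_ties(y)
    ties = (tx or ty) if tie_policy == "either" else (tx and ty)
    method = "pearson" if ties else "spearman"

    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(
            f"constant vector in pair ({x_name}, {y_name}); coefficient undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return CorrelationResult(x_name, y_name, float("nan"), method, float("nan"), n, ties)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            r, p = sps.spearmanr(x, y)
        else:
            r, p = sps.pearsonr(x, y)
    # a perfect monotone association degenerates the t-statistic; report the
    # smallest nonzero p rather than 0 so p stays in (0, 1]
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return CorrelationResult(x_name, y_name, float(r), method, p, n, ties)


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bh":
        return sps.false_discovery_control(p, method="bh")
    if method == "holm":
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def correlation_matrix(
    indicators: pd.DataFrame,
    externals: pd.DataFrame,
    alpha: float = 0.05,
    tie_policy: str = "either",
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every indicator column with every external-variable column.

    Both tables must carry a ``report_id`` column (or index) to join on.
    Returns ``(results, edges)``: a long-format table with one row per
    (indicator, variable) pair, and the significant edge list (p < alpha
    after the optional adjustment), signed by the coefficient.
    """
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {ADJUSTMENTS}")

    def _indexed(df: pd.DataFrame) -> pd.DataFrame:
        return df.set_index("report_id") if "report_id" in df.columns else df

    ind = _indexed(indicators)
    ext = _indexed(externals)
    joined = ind.join(ext, how="inner", lsuffix="", rsuffix="_ext")
    if joined.empty:
        raise ValueError("no report_ids in common between indicators and externals")

    rows = []
    for ind_col in ind.columns:
        for ext_col in ext.columns:
            res = correlate(
                joined[ind_col].to_numpy(),
                joined[ext_col + "_ext" if ext_col + "_ext" in joined else ext_col].to_numpy(),
                tie_policy=tie_policy,
                x_name=ind_col,
                y_name=ext_col,
            )
            rows.append(res)

    results = pd.DataFrame(
        [
            {
                "indicator": r.x_name,
                "variable": r.y_name,
                "coefficient": r.coefficient,
                "method": r.method,
                "p_value": r.p_value,
                "n": r.n,
                "ties_present": r.ties_present,
            }
            for r in rows
        ]
    )
    p = results["p_value"].to_numpy()
    if adjust is not None:
        ok = np.isfinite(p)
        p_adj = np.full_like(p, np.nan)
        p_adj[ok] = _adjust_pvalues(p[ok], adjust)
        results["p_adjusted"] = p_adj
        p_for_sig = p_adj
    else:
        p_for_sig = p
    results["significant"] = np.where(np.isfinite(p_for_sig), p_for_sig < alpha, False)

    edges = results.loc[results["significant"], ["indicator", "variable", "coefficient"]].copy()
    edges["sign"] = np.sign(edges["coefficient"]).astype(int)
    edges = edges.reset_index(drop=True)
    return results, edges
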