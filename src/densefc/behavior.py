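"""Daily behavioral factor construction.

PANAS affect scoring, daily aggregation of sensor streams, mean imputation,
and the collinearity screen (VIF then pairwise rank correlation) applied
before any regression modeling.
"""

from __future__ import annotations

import numbers
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NEGATIVE_ITEMS",
    "POSITIVE_ITEMS",
    "panas_scores",
    "daily_aggregate",
    "impute_mean",
    "collinearity_screen",
]

#: PANAS items whose sum gives the negative-affect (NAF) score.
NEGATIVE_ITEMS = ("afraid", "nervous", "upset", "hostile", "ashamed")
#: PANAS items whose sum gives the positive-affect (PAF) score.
POSITIVE_ITEMS = ("active", "determined", "attentive", "inspired", "alert")


def panas_scores(response: Mapping[str, object]) -> tuple[float, float]:
    """Sum the five negative and five positive PANAS items of one response.

    A score whose items are not all present comes back as NaN (missing), never
    as a zero-filled partial sum.
    """

    def score(items):
        vals = []
        for item in items:
            v = response.get(item)
            if v is None or (isinstance(v, numbers.Real) and np.isnan(v)):
                return float("nan")
            vals.append(float(v))
        return float(sum(vals))

    return score(NEGATIVE_ITEMS), score(POSITIVE_ITEMS)


_AGG_FUNS = {
    "mean": np.mean,
    "median": np.median,
    "min": np.min,
    "max": np.max,
    # SD of a single sample is 0 by convention so sparse-sensor columns stay
    # aligned with their mean/max companions.
    "sd": lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
}


def daily_aggregate(
    samples: pd.DataFrame,
    statistics: Iterable[str] = ("mean",),
    value_col: str = "value",
    time_col: str = "timestamp",
) -> pd.DataFrame:
    """Collapse a timestamped sample stream to one row per calendar day.

    Parameters
    ----------
    samples : DataFrame with a timestamp column and a value column.
    statistics : subset of {mean, median, min, max, sd}.

    Days inside the observed span that received no samples are present with
    NaN (missing) in every statistic column.
    """
    statistics = list(statistics)
    for s in statistics:
        if s not in _AGG_FUNS:
            raise ValueError(f"unknown statistic {s!r}; choose from {sorted(_AGG_FUNS)}")
    ts = pd.to_datetime(samples[time_col])
    days = ts.dt.normalize()
    grouped = samples[value_col].astype(float).groupby(days)
    out = pd.DataFrame({s: grouped.apply(_AGG_FUNS[s]) for s in statistics})
    if len(out):
        full = pd.date_range(out.index.min(), out.index.max(), freq="D")
        out = out.reindex(full)
    out.index.name = "day"
    return out


def impute_mean(series: pd.Series) -> pd.Series:
    """Replace missing values with the mean of the observed ones.

    Observed cells are untouched, so the series mean is preserved exactly.
    """
    observed = series.dropna()
    if observed.empty:
        raise ValueError("cannot impute an all-missing series")
    return series.fillna(observed.mean())


def _vif(X: np.ndarray, j: int) -> float:
    """1 / (1 - R^2) of column j regressed on the remaining columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return np.inf
    r2 = 1 - resid @ resid / tss
    return np.inf if r2 >= 1 else 1.0 / (1.0 - r2)


def collinearity_screen(
    table: pd.DataFrame,
    vif_threshold: float = 5.0,
    corr_threshold: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[list[str], dict]:
    """Drop collinear factors: zero-variance, then VIF, then rank correlation.

    The screen runs in three passes, each recorded in the report:

    1. constant columns are dropped (VIF undefined);
    2. while any variance inflation factor exceeds ``vif_threshold``, the
       factor with the largest VIF is dropped;
    3. for every remaining pair with \\|Spearman rho\\| > ``corr_threshold``,
       the variable earlier in ``priority`` (default: column order) is kept
       and the other dropped.

    Returns the retained column names (original order) and a report dict with
    one entry per drop (name, rule, trigger value).  The screen is idempotent:
    applying it to its own output drops nothing further.
    """
    if table.isna().any().any():
        raise ValueError("impute the table before screening")
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 factors to screen")
    priority = list(priority) if priority is not None else cols
    rank = {c: priority.index(c) if c in priority else len(priority) + i
            for i, c in enumerate(cols)}
    drops: list[dict] = []

    kept = [c for c in cols]
    for c in cols:
        if table[c].nunique() <= 1:
            kept.remove(c)
            drops.append({"name": c, "rule": "zero variance", "value": 0.0})

    while len(kept) >= 2:
        X = table[kept].to_numpy(float)
        vifs = np.array([_vif(X, j) for j in range(len(kept))])
        worst = int(np.argmax(vifs))
        if vifs[worst] > vif_threshold:
            drops.append({"name": kept[worst], "rule": "vif", "value": float(vifs[worst])})
            kept.pop(worst)
        else:
            break

    changed = True
    while changed and len(kept) >= 2:
        changed = False
        rho = stats.spearmanr(table[kept].to_numpy(float)).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if abs(rho[a, b]) > corr_threshold:
                    loser = kept[b] if rank[kept[a]] <= rank[kept[b]] else kept[a]
                    drops.append(
                        {"name": loser, "rule": "correlation", "value": float(rho[a, b])}
                    )
                    kept.remove(loser)
                    changed = True
                    break
            if changed:
                break

    report = {
        "vif_threshold": vif_threshold,
        "corr_threshold": corr_threshold,
        "dropped": drops,
        "retained": kept,
    }
    return kept, report
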