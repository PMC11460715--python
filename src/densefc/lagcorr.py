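"""Time-lagged brain-behavior cross-correlation with surrogate nulls.

For each network metric series (sampled on scan days) and each daily
behavioral factor, the correlation between metric(d) and factor(d - lag) is
computed for lags of 1 to 15 days.  Significance comes from surrogate
factor series built by randomizing the Fourier phases of the daily factor
(amplitude spectrum, and hence autocovariance, preserved) on the full daily
grid, then subsampled to the scan days exactly like the original.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .permstats import bh_fdr

__all__ = [
    "LAG_GRID",
    "align_lag",
    "phase_surrogate",
    "surrogate_test",
    "lag_analysis",
]

#: The fixed lag grid in days (the previous-day design covers lag 0).
LAG_GRID = tuple(range(1, 16))


def align_lag(
    session_days: np.ndarray, factor: pd.Series, lag: int
) -> np.ndarray:
    """Factor values lag days before each session day.

    Raises if the lag is outside the fixed 1..15-day grid or a required day
    is absent from the factor series.
    """
    if lag not in LAG_GRID:
        raise ValueError(f"lag must be in {LAG_GRID[0]}..{LAG_GRID[-1]}, got {lag}")
    days = np.asarray(session_days, int) - lag
    missing = [d for d in days if d not in factor.index]
    if missing:
        raise ValueError(f"factor series lacks day(s) {missing}")
    return factor.loc[days].to_numpy(float)


def phase_surrogate(
    series: np.ndarray, seed: int | None = None, n_surrogates: int = 1
) -> np.ndarray:
    """Spectral-synthesis surrogates: same amplitude spectrum, random phases.

    The real FFT phases of all strictly positive, non-Nyquist frequencies are
    replaced by uniform draws (conjugate symmetry implied by the real inverse
    transform); DC and Nyquist stay fixed so the output is real and the mean
    is preserved exactly.  Returns shape (n_surrogates, n) or (n,) when a
    single surrogate is requested.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 4:
        raise ValueError("series must have length >= 4")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    n_freq = spec.size
    phases = rng.uniform(0, 2 * np.pi, size=(n_surrogates, n_freq))
    phases[:, 0] = np.angle(spec[0])
    if n % 2 == 0:  # Nyquist bin must stay real
        phases[:, -1] = np.angle(spec[-1])
    out = np.fft.irfft(amp[None, :] * np.exp(1j * phases), n=n)
    return out[0] if n_surrogates == 1 else out


def surrogate_test(
    metric_series: pd.Series,
    factor_series: pd.Series,
    lags=LAG_GRID,
    n_surr: int = 10000,
    seed: int | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Observed lagged correlations with phase-surrogate p-values.

    ``metric_series`` is indexed by session day, ``factor_series`` by
    calendar day.  Surrogate factors are synthesized on the full daily grid
    and subsampled to the session days with the same lag arithmetic as the
    observed factor, preserving the irregular twice-weekly sampling.  p-values
    are two-sided on |rho| with the add-one rule.  A constant metric series
    makes rho undefined; the result rows carry NaN and a flag rather than 0.
    """
    if n_surr < 100:
        warnings.warn("n_surr < 100 gives unstable p-values", stacklevel=2)
    corr = {"pearson": _pearson_rows, "spearman": _spearman_rows}[method]
    session_days = metric_series.index.to_numpy(int)
    m = metric_series.to_numpy(float)
    m_sd = m.std()
    surr = phase_surrogate(factor_series.to_numpy(float), seed=seed,
                           n_surrogates=max(n_surr, 2))
    day_pos = {int(d): k for k, d in enumerate(factor_series.index)}
    rows = []
    for lag in lags:
        f = align_lag(session_days, factor_series, lag)
        if m_sd == 0 or f.std() == 0:
            rows.append({"lag": lag, "rho": np.nan, "p": np.nan, "degenerate": True})
            continue
        rho = corr(m[None, :], f)[0]
        cols = [day_pos[int(d) - lag] for d in session_days]
        f_null = surr[:n_surr, :][:, cols]
        rho_null = corr(f_null, m)
        p = (1.0 + np.sum(np.abs(rho_null) >= abs(rho))) / (1.0 + n_surr)
        rows.append({"lag": lag, "rho": float(rho), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


def _pearson_rows(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``vec``."""
    r = rows - rows.mean(axis=1, keepdims=True)
    v = vec - vec.mean()
    denom = np.sqrt((r**2).sum(axis=1) * (v**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (r @ v) / denom


def _spearman_rows(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rr = stats.rankdata(rows, axis=1)
    rv = stats.rankdata(vec)
    return _pearson_rows(rr, rv)


def lag_analysis(
    metric_table: pd.DataFrame,
    behavior: pd.DataFrame,
    factors: list[str],
    networks: list[str],
    metric: str = "efficiency",
    threshold: float = 0.10,
    lags=LAG_GRID,
    n_surr: int = 10000,
    seed: int | None = None,
    correct_across_lags: bool = False,
) -> pd.DataFrame:
    """Run the surrogate test per network and BH-correct per factor-lag pair.

    The correction family is the set of networks for each (factor, lag) tuple,
    treating tuples as independent; ``correct_across_lags`` switches to the
    stricter networks x lags family per factor.
    """
    sub = metric_table[
        (metric_table["metric"] == metric) & (metric_table["threshold"] == threshold)
    ]
    piv = sub.pivot_table(index="session_day", columns="network", values="value").sort_index()
    out = []
    rng = np.random.default_rng(seed)
    for factor in factors:
        for net in networks:
            res = surrogate_test(
                piv[net], behavior[factor], lags=lags, n_surr=n_surr,
                seed=int(rng.integers(2**31)),
            )
            res["network"] = net
            res["factor"] = factor
            out.append(res)
    table = pd.concat(out, ignore_index=True)
    table["metric"] = metric
    table["threshold"] = threshold
    table["q"] = np.nan
    group_cols = ["factor"] if correct_across_lags else ["factor", "lag"]
    for _, idx in table.groupby(group_cols).groups.items():
        ok = table.loc[idx, "p"].notna().to_numpy()
        if ok.any():
            sel = idx[ok]
            table.loc[sel, "q"] = bh_fdr(table.loc[sel, "p"].to_numpy())
    return table
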