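"""Standardized regression with permutation inference and BH-FDR.

The shared inferential engine: every response (a link's Fisher-z weight
series, a network metric series, or a unit's classification-accuracy
series across sessions) is regressed on standardized daily factors, the
null distribution of each predictor's t statistic is built by permuting
the response rows, and q-values control the false discovery rate within
the family the study design prescribes (links or networks per predictor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "standardize",
    "perm_lm",
    "perm_lm_batch",
    "bh_fdr",
    "align_previous_day",
    "model_links",
    "model_metrics",
]


@dataclass
class RegressionResult:
    """Per-predictor standardized coefficients with permutation p-values."""

    predictors: list[str]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None = None


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score columns to mean 0, SD 1 (ddof=1); constant columns are errors."""
    x = np.asarray(x, float)
    orig_1d = x.ndim == 1
    if orig_1d:
        x = x[:, None]
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant column(s) at index {bad}; cannot standardize")
    out = (x - x.mean(axis=0)) / sd
    return out[:, 0] if orig_1d else out


def _t_stats(design: np.ndarray, pinv: np.ndarray, diag_inv: np.ndarray,
             Y: np.ndarray, dof: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS betas and t statistics for many responses at once."""
    B = pinv @ Y                      # (p, m)
    resid = Y - design @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.outer(diag_inv, sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = B / se
    return B, t


def perm_lm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    predictors: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation regression of many responses on one shared design.

    Responses (columns of ``Y``) and predictors are z-scored; observed t
    statistics come from OLS with intercept; the null permutes response rows
    (the same permutation stream for every response, so families share one
    reference set) and two-sided p-values use the add-one rule
    p = (1 + #{|t*| >= |t|}) / (1 + n_perm).

    Returns (beta, t, p), each of shape (n_predictors, n_responses).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more observations than predictors + 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    Xs = standardize(X)
    Ys = standardize(Y)
    design = np.column_stack([np.ones(n), Xs])
    pinv = np.linalg.pinv(design)
    diag_inv = np.diag(np.linalg.inv(design.T @ design))
    dof = n - design.shape[1]

    B, t_obs = _t_stats(design, pinv, diag_inv, Ys, dof)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs[1:])       # drop intercept row
    exceed = np.zeros_like(abs_obs)
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        _, t_star = _t_stats(design, pinv, diag_inv, Ys[perm], dof)
        exceed += np.abs(t_star[1:]) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return B[1:], t_obs[1:], p


def perm_lm(
    y: np.ndarray,
    X: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    predictors: list[str] | None = None,
) -> RegressionResult:
    """Permutation regression of one response; see :func:`perm_lm_batch`."""
    X2 = np.atleast_2d(np.asarray(X, float))
    if X2.shape[0] == 1:
        X2 = X2.T
    beta, t, p = perm_lm_batch(y, X2, n_perm=n_perm, seed=seed)
    names = predictors or [f"x{j}" for j in range(X2.shape[1])]
    return RegressionResult(
        predictors=names, beta=beta[:, 0], t=t[:, 0], p=p[:, 0],
        n_perm=n_perm, seed=seed,
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, input order kept."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def align_previous_day(
    session_days: np.ndarray, behavior: pd.DataFrame, factors: list[str], lag: int = 1
) -> pd.DataFrame:
    """Factor values ``lag`` days before each session day, row-aligned.

    The default previous-day design pairs a session on day d with the factors
    of day d-1 (for sleep factors: the night ending on day d).
    """
    days = np.asarray(session_days, int) - lag
    missing = [d for d in days if d not in behavior.index]
    if missing:
        raise ValueError(f"behavior table lacks required day(s) {missing}")
    out = behavior.loc[days, factors].reset_index(drop=True)
    return out


def _batch_with_degenerate(Y, X, n_perm, seed, n_report):
    """Run perm_lm_batch, flagging constant response columns as missing.

    A response with zero variance across sessions (e.g. a saturated
    efficiency series) has no defined standardized coefficient; its rows come
    back as NaN rather than aborting the whole family.
    """
    Y = np.asarray(Y, float)
    ok = Y.std(axis=0, ddof=1) > 0
    beta = np.full((n_report, Y.shape[1]), np.nan)
    p = np.full((n_report, Y.shape[1]), np.nan)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant response column(s) flagged missing",
            stacklevel=3,
        )
    if ok.any():
        b, t, pv = perm_lm_batch(Y[:, ok], X, n_perm=n_perm, seed=seed)
        beta[:, ok] = b[:n_report]
        p[:, ok] = pv[:n_report]
    return beta, p


def _fdr_rows(p: np.ndarray) -> np.ndarray:
    """BH per row, ignoring missing entries."""
    q = np.full_like(p, np.nan)
    for j in range(p.shape[0]):
        ok = np.isfinite(p[j])
        if ok.any():
            q[j, ok] = bh_fdr(p[j, ok])
    return q


def _tidy(unit_ids, predictors, beta, p, q, n_perm, extra=None) -> pd.DataFrame:
    rows = []
    for u, unit in enumerate(unit_ids):
        for j, pred in enumerate(predictors):
            row = {
                "unit": unit,
                "factor": pred,
                "beta": float(beta[j, u]),
                "p": float(p[j, u]),
                "q": float(q[j, u]),
                "n_perm": n_perm,
            }
            if extra:
                row.update(extra)
            rows.append(row)
    return pd.DataFrame(rows)


def model_links(
    adjacencies,
    atlas: pd.DataFrame,
    behavior: pd.DataFrame,
    factors: list[str],
    networks: list[str],
    covariates: list[str] | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    lag: int = 1,
) -> pd.DataFrame:
    """Previous-day regression of every within-network link on the factors.

    Link weights are taken on the Fisher-z scale.  The FDR family is, per
    predictor, the set of links of the chosen subnetworks.  Covariates (e.g.
    in-scanner prolonged eye closure) enter the design but are not corrected
    or reported as hypotheses.
    """
    from .connectivity import adjacency_stack, fisher

    adjacencies = list(adjacencies)
    zs = [a if a.domain == "fisher_z" else fisher(a) for a in adjacencies]
    stack = adjacency_stack(zs)
    session_days = np.array([a.session_day for a in adjacencies])
    X = align_previous_day(session_days, behavior, factors + (covariates or []), lag)

    communities = atlas["network"].to_numpy()
    links = []
    for net in networks:
        nodes = np.where(communities == net)[0]
        for ai in range(len(nodes)):
            for bi in range(ai + 1, len(nodes)):
                links.append((int(nodes[ai]), int(nodes[bi]), net))
    Y = np.column_stack([stack[:, i, j] for i, j, _ in links])
    n_factors = len(factors)
    beta, p = _batch_with_degenerate(Y, X.to_numpy(), n_perm, seed, n_factors)
    q = _fdr_rows(p)
    tidy = _tidy([f"{i}-{j}" for i, j, _ in links], factors, beta, p, q, n_perm)
    tidy["network"] = np.repeat([net for _, _, net in links], n_factors)
    return tidy


def model_metrics(
    metric_table: pd.DataFrame,
    behavior: pd.DataFrame,
    factors: list[str],
    covariates: list[str] | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
    lag: int = 1,
) -> pd.DataFrame:
    """Previous-day regression of each network metric series on the factors.

    One model per (network, metric, threshold); the FDR family is, per
    predictor, the set of networks within each metric x threshold slice,
    matching the study's correction over the number of networks.
    """
    out = []
    for (metric, thr), sub in metric_table.groupby(["metric", "threshold"]):
        piv = sub.pivot_table(index="session_day", columns="network", values="value")
        piv = piv.sort_index()
        X = align_previous_day(
            piv.index.to_numpy(), behavior, factors + (covariates or []), lag
        )
        n_factors = len(factors)
        beta, p = _batch_with_degenerate(piv.to_numpy(), X.to_numpy(), n_perm, seed,
                                         n_factors)
        q = _fdr_rows(p)
        tidy = _tidy(list(piv.columns), factors, beta, p, q, n_perm)
        tidy["metric"] = metric
        tidy["threshold"] = thr
        out.append(tidy)
    return pd.concat(out, ignore_index=True)
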