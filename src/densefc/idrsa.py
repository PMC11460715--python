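"""Inter-daily representational similarity analysis.

Adapts the intersubject-correlation framework to a single densely sampled
subject: each scan day plays the role of one "subject", so for every ROI a
day-by-day similarity matrix is the pairwise correlation of that ROI's time
course across sessions (all sessions censored with the same shared mask so
their time axes are comparable).  The behavioral side is cast as either a
nearest-neighbors structure (days with similar factor values are alike) or
an Anna-Karenina structure (high-scoring days are alike, low-scoring days
are each idiosyncratic), and the two matrices are compared with a Mantel
permutation test on a rank statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .permstats import bh_fdr

__all__ = [
    "roi_isc",
    "behavior_similarity",
    "mantel",
    "idrsa_analysis",
]


def roi_isc(
    sessions: list[np.ndarray], roi: int, keep: np.ndarray
) -> np.ndarray:
    """Day-by-day correlation matrix for one ROI's time course.

    Every session must be censored with the same shared keep-mask; with
    fewer than 3 retained volumes the correlation is meaningless and a
    looser scrubbing percentage is needed.
    """
    keep = np.asarray(keep, bool)
    if keep.sum() < 3:
        raise ValueError(
            "fewer than 3 retained volumes under the shared mask; "
            "use a looser scrubbing percentage"
        )
    courses = np.column_stack([np.asarray(s, float)[keep, roi] for s in sessions])
    r = np.corrcoef(courses, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def behavior_similarity(values: np.ndarray, model: str = "nn") -> np.ndarray:
    """Day-by-day behavioral similarity under the NN or AK structure.

    Values are rank-transformed (average ranks on ties) and scaled to
    [0, 1].  NN: sim(i, j) = -|r_i - r_j| (0 is maximal similarity);
    AK: sim(i, j) = (r_i + r_j) / 2, so two top-ranked days reach 1 while
    low-ranked days are dissimilar to everyone including each other.
    """
    v = np.asarray(values, float)
    n = v.size
    ranks = stats.rankdata(v)
    r = (ranks - 1) / (n - 1) if n > 1 else np.zeros(1)
    if model == "nn":
        sim = -np.abs(r[:, None] - r[None, :])
    elif model == "ak":
        sim = (r[:, None] + r[None, :]) / 2.0
    else:
        raise ValueError("model must be 'nn' or 'ak'")
    return sim


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    sim_a: np.ndarray,
    sim_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: rank correlation of two similarity matrices.

    The statistic is the Spearman correlation of the vectorized upper
    triangles; the null simultaneously permutes rows and columns of the
    second matrix; p uses the add-one rule.  One-sided positive by default
    (the working hypothesis is that days more alike behaviorally are more
    alike neurally); ``alternative='two-sided'`` tests |rho|.
    """
    a = np.asarray(sim_a, float)
    b = np.asarray(sim_b, float)
    n = a.shape[0]
    if a.shape != b.shape or a.shape != (n, n):
        raise ValueError("matrices must be square with matching shapes")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    ua, ub = _upper(a), _upper(b)
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        raise ValueError("constant upper triangle; Mantel statistic undefined")
    ra = stats.rankdata(ua)
    rb = stats.rankdata(ub)
    ra = (ra - ra.mean()) / ra.std()
    rb = (rb - rb.mean()) / rb.std()
    rho = float(ra @ rb / ra.size)

    # A row/column permutation of B permutes the unordered pairs of its upper
    # triangle; precompute the pair -> position lookup to apply it to ranks.
    iu = np.triu_indices(n, k=1)
    lin = np.zeros((n, n), int)
    lin[iu] = np.arange(iu[0].size)
    lin = lin + lin.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pair_perm = lin[perm[iu[0]], perm[iu[1]]]
        rho_star = float(ra @ rb[pair_perm] / ra.size)
        if alternative == "greater":
            count += rho_star >= rho
        else:
            count += abs(rho_star) >= abs(rho)
    p = (1.0 + count) / (1.0 + n_perm)
    return rho, p


def idrsa_analysis(
    sessions: list[np.ndarray],
    behavior_values: np.ndarray,
    keep: np.ndarray,
    rois=None,
    models: tuple[str, ...] = ("nn", "ak"),
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel tests per ROI and model, BH-corrected across ROIs per model."""
    n_rois = sessions[0].shape[1]
    rois = range(n_rois) if rois is None else rois
    rng = np.random.default_rng(seed)
    rows = []
    for model in models:
        sim_b = behavior_similarity(behavior_values, model)
        for roi in rois:
            sim_a = roi_isc(sessions, roi, keep)
            rho, p = mantel(sim_a, sim_b, n_perm=n_perm, seed=int(rng.integers(2**31)))
            rows.append({"roi": roi, "model": model, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for model, idx in out.groupby("model").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
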