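"""Per-session connectivity estimation.

Rest and movie runs use full-run Pearson correlation between ROI time
courses; task runs use beta-series correlation (one HRF-convolved regressor
per trial, least-squares-all).  Link weights are Fisher-transformed, the
session-level mean framewise displacement is regressed out of every link
across sessions, and the result is mapped back to the correlation scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Adjacency",
    "pearson_adjacency",
    "fit_beta_series",
    "beta_adjacency",
    "fisher",
    "fisher_inverse",
    "residualize_motion",
    "adjacency_stack",
    "upper_links",
]

_CLIP = 1.0 - 1e-7


@dataclass
class Adjacency:
    """Symmetric weighted ROI x ROI matrix for one session."""

    weights: np.ndarray
    domain: str = "r"          # "r" or "fisher_z"
    session_day: int = 0
    task: str = "rest"

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def _corr_matrix(samples: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows of (observations x variables)."""
    x = np.asarray(samples, float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance column(s); links set to NaN",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return r


def pearson_adjacency(
    data: np.ndarray,
    keep: np.ndarray | None = None,
    session_day: int = 0,
    task: str = "rest",
) -> Adjacency:
    """Correlation adjacency over retained volumes.

    The same keep-mask applies to every ROI so censoring stays pairwise
    consistent.  Needs at least 3 retained volumes.
    """
    x = np.asarray(data, float)
    if keep is not None:
        x = x[np.asarray(keep, bool)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 retained volumes")
    return Adjacency(_corr_matrix(x), "r", session_day, task)


def _glover_design(
    onsets: np.ndarray, n_volumes: int, tr_seconds: float, durations: np.ndarray
) -> np.ndarray:
    """One HRF-convolved column per trial on the scan time grid."""
    from nilearn.glm.first_level import compute_regressor

    frame_times = np.arange(n_volumes) * tr_seconds
    cols = []
    for onset, dur in zip(onsets, durations):
        cond = np.array([[onset], [dur], [1.0]])
        reg, _ = compute_regressor(cond, "glover", frame_times)
        cols.append(reg[:, 0])
    return np.column_stack(cols)


def fit_beta_series(
    data: np.ndarray,
    trials,
    tr_seconds: float,
    durations: float | np.ndarray = 0.5,
    drift_order: int = 1,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Least-squares-all trial amplitude estimates per ROI.

    Every trial gets its own canonical (double-gamma) HRF regressor and all
    trials are fit simultaneously alongside an intercept and polynomial drift
    columns.  A near-singular design (heavily overlapping trials) triggers a
    warning and a small ridge penalty on the trial block.

    Returns a (n_trials x n_rois) beta matrix.
    """
    x = np.asarray(data, float)
    onsets = np.asarray(trials["onset_s"], float)
    duration = x.shape[0] * tr_seconds
    if (onsets < 0).any() or (onsets >= duration).any():
        raise ValueError("trial onsets must fall within the run duration")
    if np.isscalar(durations):
        durations = np.full(len(onsets), float(durations))
    trial_block = _glover_design(onsets, x.shape[0], tr_seconds, durations)
    t = np.arange(x.shape[0]) / max(x.shape[0] - 1, 1)
    drift = np.column_stack([t**k for k in range(drift_order + 1)])
    design = np.column_stack([trial_block, drift])
    cond = np.linalg.cond(design)
    gram = design.T @ design
    if cond > 1e8:
        warnings.warn(
            f"design condition number {cond:.2e}; applying ridge fallback",
            stacklevel=2,
        )
        gram = gram + ridge * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0])
    beta = np.linalg.solve(gram, design.T @ x)
    return beta[: trial_block.shape[1]]


def beta_adjacency(
    betas: np.ndarray, session_day: int = 0, task: str = "pvt"
) -> Adjacency:
    """Correlate per-trial amplitudes across trials between ROIs."""
    b = np.asarray(betas, float)
    if b.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    return Adjacency(_corr_matrix(b), "r", session_day, task)


def fisher(adj: Adjacency) -> Adjacency:
    """Variance-stabilizing z = atanh(r); |r| = 1 clipped just inside."""
    if adj.domain != "r":
        raise ValueError("fisher expects an r-domain adjacency")
    z = np.arctanh(np.clip(adj.weights, -_CLIP, _CLIP))
    return Adjacency(z, "fisher_z", adj.session_day, adj.task)


def fisher_inverse(adj: Adjacency) -> Adjacency:
    """Map Fisher z back to the correlation scale."""
    if adj.domain != "fisher_z":
        raise ValueError("fisher_inverse expects a fisher_z adjacency")
    return Adjacency(np.tanh(adj.weights), "r", adj.session_day, adj.task)


def adjacency_stack(adjacencies: list[Adjacency]) -> np.ndarray:
    """Stack session matrices into (n_sessions, n, n), checking domains agree."""
    domains = {a.domain for a in adjacencies}
    if len(domains) != 1:
        raise ValueError("mixed adjacency domains")
    return np.stack([a.weights for a in adjacencies])


def residualize_motion(
    adjacencies: list[Adjacency], mean_fd: np.ndarray
) -> list[Adjacency]:
    """Regress session-level mean FD out of every link across sessions.

    Input must be Fisher-z.  Mean FD is centered, so each link's output keeps
    its across-session mean (intercept) plus the FD-orthogonal residual; the
    result is mapped back to the r scale, preserving interpretability as
    connectivity.  Constant FD across sessions degenerates to the identity.
    """
    if any(a.domain != "fisher_z" for a in adjacencies):
        raise ValueError("residualize_motion expects fisher_z adjacencies")
    fd = np.asarray(mean_fd, float)
    z = adjacency_stack(adjacencies)
    s = z.shape[0]
    if fd.shape != (s,):
        raise ValueError("need one mean-FD value per session")
    fd_c = fd - fd.mean()
    if np.allclose(fd_c, 0):
        warnings.warn("mean FD constant across sessions; residualization is identity",
                      stacklevel=2)
        out_z = z
    else:
        flat = z.reshape(s, -1)
        slope = (fd_c @ flat) / (fd_c @ fd_c)
        out_z = (flat - np.outer(fd_c, slope)).reshape(z.shape)
    return [
        fisher_inverse(Adjacency(out_z[k], "fisher_z", a.session_day, a.task))
        for k, a in enumerate(adjacencies)
    ]


def upper_links(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle (link ordering)."""
    return np.triu_indices(n, k=1)
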