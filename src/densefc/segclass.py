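"""Between-days time-segment identification for naturalistic (movie) runs.

The movie run of every session is cut into overlapping sliding-window
segments (25 TRs, step 1 TR by default; 14.85 s at TR 0.594 s).  For one
spatial unit (an ROI, or a set of ROIs standing in for a searchlight
sphere), a leave-one-session-out classifier matches each held-out segment
to the segment position whose cross-session average template correlates
best with it; accuracy is the fraction of segments identified correctly,
against a chance level of 1 / n_segments.  Per-unit accuracy maps across
sessions are then regressed on lagged behavioral factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .permstats import _batch_with_degenerate, _fdr_rows, align_previous_day

__all__ = [
    "SegmentSet",
    "make_segments",
    "chance_level",
    "loo_identify",
    "accuracy_map",
    "accuracy_regression",
]


@dataclass
class SegmentSet:
    """Sliding-window segments of one session for one unit.

    ``patterns`` has shape (n_segments, n_unit_rois * window): segment k
    covers TRs [k*step, k*step + window), flattened over the unit's ROIs.
    """

    patterns: np.ndarray
    starts: np.ndarray
    window: int
    step: int

    @property
    def n_segments(self) -> int:
        return self.patterns.shape[0]


def make_segments(
    series: np.ndarray,
    window: int = 25,
    step: int = 1,
    rois=None,
    keep: np.ndarray | None = None,
) -> SegmentSet:
    """Cut a (volumes x ROI) series into overlapping segments.

    The segment count is floor((T - window) / step) + 1; a 970-volume run
    with window 25 and step 1 yields 946 segments.  When a censor mask is
    given, segments containing any censored volume are dropped (their starts
    are removed from the grid), keeping grids identical across sessions that
    share the mask.
    """
    x = np.asarray(series, float)
    T = x.shape[0]
    if T < window:
        raise ValueError(f"run of {T} volumes shorter than window {window}")
    if rois is not None:
        x = x[:, np.atleast_1d(rois)]
    n_seg = (T - window) // step + 1
    starts = np.arange(n_seg) * step
    if keep is not None:
        keep = np.asarray(keep, bool)
        valid = np.array([keep[s : s + window].all() for s in starts])
        starts = starts[valid]
    patterns = np.stack([x[s : s + window].T.ravel() for s in starts]) if len(starts) \
        else np.empty((0, x.shape[1] * window))
    return SegmentSet(patterns=patterns, starts=starts, window=window, step=step)


def chance_level(n_segments: int) -> float:
    """Uniform-guessing accuracy among n segments."""
    if n_segments < 1:
        raise ValueError("need at least one segment")
    return 1.0 / n_segments


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Correlation matrix between rows of A and rows of B (zero-var -> -inf)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((Ac**2).sum(axis=1))
    b_sd = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (Ac @ Bc.T) / np.outer(a_sd, b_sd)
    c[~np.isfinite(c)] = -np.inf
    return c


def loo_identify(segment_sets: list[SegmentSet]) -> np.ndarray:
    """Leave-one-session-out segment identification accuracy per session.

    For each held-out session, the template for position m is the mean
    pattern of the remaining sessions' segment m; each held-out segment n is
    assigned to the position whose template it correlates with most
    (ties -> smallest position).  Returns one accuracy per session.
    """
    if len(segment_sets) < 2:
        raise ValueError("need at least 2 sessions")
    shapes = {s.patterns.shape for s in segment_sets}
    if len(shapes) != 1:
        raise ValueError("sessions must share an identical segment grid")
    stack = np.stack([s.patterns for s in segment_sets])  # (S, n_seg, d)
    S, n_seg, _ = stack.shape
    total = stack.sum(axis=0)
    acc = np.empty(S)
    truth = np.arange(n_seg)
    for s in range(S):
        template = (total - stack[s]) / (S - 1)
        corr = _corr_rows(stack[s], template)
        predicted = corr.argmax(axis=1)
        acc[s] = (predicted == truth).mean()
    return acc


def accuracy_map(
    sessions: list[np.ndarray],
    units: list,
    window: int = 25,
    step: int = 1,
    keep: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (session, unit) identification accuracy table.

    ``units`` is a list of ROI index arrays (a single index per unit gives
    ROI-wise maps); all sessions use the same censor mask so segment grids
    match.
    """
    rows = []
    n_segments = None
    for u, roi_idx in enumerate(units):
        sets = [make_segments(s, window, step, rois=roi_idx, keep=keep) for s in sessions]
        n_segments = sets[0].n_segments
        acc = loo_identify(sets)
        for s, a in enumerate(acc):
            rows.append({"session": s, "unit": u, "accuracy": float(a)})
    out = pd.DataFrame(rows)
    out.attrs["n_segments"] = n_segments
    out.attrs["chance"] = chance_level(n_segments) if n_segments else np.nan
    return out


def accuracy_regression(
    accuracy: pd.DataFrame,
    session_days: np.ndarray,
    behavior: pd.DataFrame,
    factors: list[str],
    lag: int = 1,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Regress per-unit accuracy series on lagged factors, FDR across units."""
    piv = accuracy.pivot_table(index="session", columns="unit", values="accuracy")
    piv = piv.sort_index()
    X = align_previous_day(np.asarray(session_days, int), behavior, factors, lag)
    beta, p = _batch_with_degenerate(piv.to_numpy(), X.to_numpy(), n_perm, seed,
                                     len(factors))
    rows = []
    q = _fdr_rows(p)
    for u, unit in enumerate(piv.columns):
        for j, fac in enumerate(factors):
            rows.append(
                {
                    "unit": unit,
                    "factor": fac,
                    "beta": float(beta[j, u]),
                    "p": float(p[j, u]),
                    "q": float(q[j, u]),
                }
            )
    return pd.DataFrame(rows)
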