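"""Signal conditioning and motion scrubbing for ROI time series.

The cleaning chain applied to every session after standard image
preprocessing: Savitzky-Golay detrending (240 s window by default),
confound residualization (confounds detrended with the same filter first),
and a 0.01 Hz high-pass realized as a discrete-cosine basis projection.
Motion censoring supports both ordinary (per-session union) scrubbing and
the percentage-based shared-mask variant needed when sessions must keep
comparable time axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import dct, idct

__all__ = [
    "CensorMask",
    "savgol_detrend",
    "regress_confounds",
    "highpass",
    "flag_volumes",
    "scrub_union",
    "scrub_percentage",
    "clean_session",
]


@dataclass
class CensorMask:
    """Boolean keep-mask over volumes plus the rule that produced it."""

    keep: np.ndarray
    threshold: float = 0.2
    rule: str = "ordinary"
    pct: float | None = None

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, float)
    if x.ndim == 1:
        return x[:, None], True
    return x, False


def savgol_window_length(window_seconds: float, tr_seconds: float, polyorder: int) -> int:
    """Window length in volumes: nearest odd integer >= polyorder + 2."""
    n = int(round(window_seconds / tr_seconds))
    if n % 2 == 0:
        n += 1
    return max(n, polyorder + 2 + ((polyorder + 2) % 2 == 0))


def savgol_detrend(
    series: np.ndarray,
    tr_seconds: float,
    window_seconds: float = 240.0,
    polyorder: int = 3,
) -> np.ndarray:
    """Remove the Savitzky-Golay smoothed baseline, keeping the per-ROI mean.

    The smoother tracks slow scanner drift; subtracting it and re-adding the
    column mean leaves fluctuations around a stable level.  Constant and
    low-order polynomial inputs pass through (interior samples) unchanged.
    """
    x, squeeze = _as_2d(series)
    win = savgol_window_length(window_seconds, tr_seconds, polyorder)
    if win > x.shape[0]:
        raise ValueError(
            f"series of {x.shape[0]} volumes shorter than the {win}-volume "
            f"window; use a smaller window_seconds"
        )
    baseline = signal.savgol_filter(x, win, polyorder, axis=0, mode="interp")
    resid = x - baseline
    out = resid - resid.mean(axis=0, keepdims=True) + x.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS-residualize every ROI on the confound columns (plus intercept).

    Rank-deficient confound matrices lose their dependent columns with a
    warning before fitting.  The per-ROI mean is restored afterwards.
    """
    x, squeeze = _as_2d(series)
    c, _ = _as_2d(confounds)
    if c.shape[0] != x.shape[0]:
        raise ValueError("confounds and series must have equal volume counts")
    design = np.column_stack([np.ones(x.shape[0]), c])
    # drop linearly dependent columns (diagonal of R in a QR factorization)
    _, rmat = np.linalg.qr(design)
    diag = np.abs(np.diag(rmat))
    keep_cols = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep_cols.all():
        warnings.warn("dropping linearly dependent confound columns", stacklevel=2)
        design = design[:, keep_cols]
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    out = resid + x.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def highpass(series: np.ndarray, tr_seconds: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """High-pass by zeroing discrete-cosine components below the cutoff.

    DCT component k of an N-volume series oscillates at k / (2 N TR) Hz; all
    components with 0 < f < cutoff are removed.  The DC term is kept, so the
    per-ROI mean is preserved and a constant series passes through unchanged.
    Zero phase distortion; exact projection.
    """
    x, squeeze = _as_2d(series)
    n = x.shape[0]
    nyquist = 0.5 / tr_seconds
    if cutoff_hz >= nyquist:
        raise ValueError("cutoff must be below the Nyquist frequency")
    coefs = dct(x, axis=0, norm="ortho")
    freqs = np.arange(n) / (2.0 * n * tr_seconds)
    kill = (freqs > 0) & (freqs < cutoff_hz)
    coefs[kill] = 0.0
    out = idct(coefs, axis=0, norm="ortho")
    return out[:, 0] if squeeze else out


def flag_volumes(fd: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Motion flags: strictly FD > threshold (a volume at exactly 0.2 stays)."""
    fd = np.asarray(fd, float)
    if (fd < 0).any():
        raise ValueError("framewise displacement must be nonnegative")
    return fd > threshold


def scrub_union(flag_matrix: np.ndarray, threshold: float = 0.2) -> CensorMask:
    """Ordinary shared scrubbing: censor a volume flagged in ANY session."""
    flags = np.asarray(flag_matrix, bool)
    return CensorMask(keep=~flags.any(axis=0), threshold=threshold, rule="ordinary")


def scrub_percentage(
    flag_matrix: np.ndarray, pct: float, threshold: float = 0.2
) -> CensorMask:
    """Percentage-based shared scrubbing.

    A volume is censored in all sessions iff it is flagged in at least
    ceil(pct * n_sessions) sessions; e.g. with 30 sessions, pct 0.10 censors
    at 3 flagged sessions and pct 0.05 at 2.  A pct low enough that the count
    threshold is 1 reduces to ordinary (union) scrubbing.
    """
    if not 0 < pct <= 1:
        raise ValueError("pct must lie in (0, 1]")
    flags = np.asarray(flag_matrix, bool)
    n_sessions = flags.shape[0]
    min_count = math.ceil(pct * n_sessions)
    censor = flags.sum(axis=0) >= min_count
    return CensorMask(keep=~censor, threshold=threshold, rule="percentage", pct=pct)


def clean_session(
    data: np.ndarray,
    tr_seconds: float,
    confounds: np.ndarray | None = None,
    window_seconds: float = 240.0,
    polyorder: int = 3,
    cutoff_hz: float = 0.01,
) -> np.ndarray:
    """Full conditioning chain: detrend, residualize confounds, high-pass.

    Confounds, when supplied, go through the same Savitzky-Golay step before
    being regressed out, so the filter cannot re-introduce drift.  Sessions
    without physiological confound recordings simply omit those columns.
    """
    out = savgol_detrend(data, tr_seconds, window_seconds, polyorder)
    if confounds is not None and np.size(confounds):
        conf = savgol_detrend(confounds, tr_seconds, window_seconds, polyorder)
        out = regress_confounds(out, conf)
    return highpass(out, tr_seconds, cutoff_hz)
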