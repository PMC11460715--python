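"""Synthetic dense-sampling data with known ground truth.

Emulates a single-subject study in which one person is scanned twice a week
(Mondays and Fridays) for 15 weeks while daily behavioral, physiological and
lifestyle factors are tracked with wearables and questionnaires.  Everything
downstream of raw-data preprocessing can be exercised on these data: ROI time
series with community (network) structure, daily autocorrelated behavioral
factors, framewise-displacement traces with motion spikes, and task trial
onsets.

Brain-behavior couplings are injected with :class:`EffectSpec`: the generating
correlation of a chosen ROI pair varies with a behavioral factor at a known
lag, on the Fisher-z scale so that it stays inside (-1, 1) for any slope.
The realized generating values are recorded so recovery can be tested against
exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "SynthConfig",
    "SyntheticBehavior",
    "SessionSeries",
    "gen_atlas",
    "gen_behavior",
    "gen_sessions",
    "gen_fd",
    "gen_trials",
    "default_session_days",
    "DEFAULT_FACTORS",
    "NETWORK_NAMES",
    "write_dataset",
]

#: Daily factor columns emulating the study's wearable / questionnaire streams
#: (sleep, physical activity, autonomic nervous system activity, mood, and the
#: in-scanner prolonged-eye-closure covariate).
DEFAULT_FACTORS = (
    "total_sleep",
    "awake_time",
    "restless",
    "steps",
    "inactive_time",
    "hrv_mean",
    "hrv_max",
    "hrv_min",
    "resp_mean",
    "resp_max",
    "naf_mean",
    "paf_mean",
    "microsleep_pct",
)

#: Canonical community names, in priority order.  The first thirteen mirror a
#: standard cortical/subcortical functional parcellation; extra communities
#: get generic names.
NETWORK_NAMES = (
    "default_mode",
    "fronto_parietal",
    "somatomotor",
    "cingulo_opercular",
    "visual",
    "auditory",
    "salience",
    "dorsal_attention",
    "ventral_attention",
    "medial_temporal",
    "parietal_memory",
    "reward",
    "basal_ganglia",
)


class InvalidConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


def default_session_days(n_sessions: int, start_day: int = 15) -> list[int]:
    """Twice-weekly scan days: a Monday/Friday pattern d, d+4, d+7, d+11, ...

    ``start_day`` leaves enough lead-in days that lags up to 15 days always
    have a defined factor value.
    """
    days = []
    week = 0
    while len(days) < n_sessions:
        days.append(start_day + 7 * week)
        if len(days) < n_sessions:
            days.append(start_day + 7 * week + 4)
        week += 1
    return days[:n_sessions]


@dataclass
class EffectSpec:
    """One injected brain-behavior coupling.

    The generating correlation of each link in ``target_links`` on session day
    d is tanh(atanh(base_corr) + slope * factor(d - lag_days)), i.e. the
    coupling is linear on the Fisher-z scale with ``slope`` per SD of the
    (standardized) factor.
    """

    target_links: list[tuple[int, int]]
    factor_name: str
    lag_days: int = 0
    slope: float = 0.0
    base_corr: float = 0.2

    def __post_init__(self):
        if self.lag_days < 0:
            raise InvalidConfigError("lag_days must be >= 0")
        if not -1 < self.base_corr < 1:
            raise InvalidConfigError("base_corr must lie in (-1, 1)")
        self.target_links = [tuple(sorted(map(int, l))) for l in self.target_links]
        if any(i == j for i, j in self.target_links):
            raise InvalidConfigError("target links must join distinct ROIs")

    def generating_corr(self, factor_value: float) -> float:
        z = np.arctanh(self.base_corr) + self.slope * factor_value
        return float(np.tanh(z))


@dataclass
class SynthConfig:
    """Study-design parameters; defaults mirror the emulated study."""

    n_sessions: int = 30
    n_days: int = 133          # 19 weeks of daily tracking
    session_days: list[int] | None = None
    n_rois: int = 300
    n_networks: int = 13
    n_time: int = 970          # volumes per run
    tr_seconds: float = 0.594
    ar_coefficient: float = 0.3
    base_within: float = 0.3   # baseline within-community correlation
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.session_days is None:
            self.session_days = default_session_days(self.n_sessions)
        self.session_days = [int(d) for d in self.session_days]
        if len(self.session_days) != self.n_sessions:
            raise InvalidConfigError("session_days length must equal n_sessions")
        if any(b <= a for a, b in zip(self.session_days, self.session_days[1:])):
            raise InvalidConfigError("session_days must be strictly increasing")
        if self.session_days and self.session_days[-1] >= self.n_days:
            raise InvalidConfigError("session_days must all be < n_days")
        if not 0 <= self.ar_coefficient < 1:
            raise InvalidConfigError("ar_coefficient must lie in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise InvalidConfigError("missing_fraction must lie in [0, 1)")
        if not 0 <= self.base_within < 1:
            raise InvalidConfigError("base_within must lie in [0, 1)")


@dataclass
class SessionSeries:
    """One session's ROI x time data (stored volumes x ROI)."""

    data: np.ndarray           # (n_time, n_rois)
    tr_seconds: float
    task: str = "rest"
    session_day: int = 0

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class SyntheticBehavior:
    """Generated daily factors: observed table (with missingness) + truth."""

    table: pd.DataFrame        # day-indexed, NaN where missing
    truth: pd.DataFrame        # same shape, no missingness


def gen_atlas(n_rois: int, n_networks: int, seed: int) -> pd.DataFrame:
    """Build an ROI table with unique coordinates and community labels.

    Labels are assigned round-robin so every community is nonempty; with
    ``n_rois == n_networks`` each community is a singleton.
    """
    if n_networks < 2:
        raise InvalidConfigError("need at least 2 networks")
    if n_rois < n_networks:
        raise InvalidConfigError("n_rois must be >= n_networks")
    rng = np.random.default_rng(seed)
    names = list(NETWORK_NAMES[:n_networks])
    names += [f"net{k:02d}" for k in range(len(names), n_networks)]
    labels = [names[i % n_networks] for i in range(n_rois)]
    # Unique coordinates: jittered integer grid in a nominal MNI-like box.
    base = np.arange(n_rois, dtype=float)
    coords = np.column_stack(
        [
            base * 1.5 - n_rois + rng.uniform(-0.4, 0.4, n_rois),
            rng.uniform(-100, 70, n_rois),
            rng.uniform(-60, 80, n_rois),
        ]
    )
    return pd.DataFrame(
        {
            "roi_id": np.arange(n_rois),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": labels,
        }
    )


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi**2) if phi else eps[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def gen_behavior(
    config: SynthConfig,
    effect_specs: list[EffectSpec] | None = None,
    seed: int | None = None,
    factor_names: tuple[str, ...] = DEFAULT_FACTORS,
) -> SyntheticBehavior:
    """Daily AR(1) factors, standardized, with MCAR missingness injected.

    Each factor is standardized to exact sample mean 0 / SD 1 before the
    missing markers are placed; the pre-missingness values are kept in
    ``truth`` so parameter recovery can be checked against the generating
    series.
    """
    effect_specs = effect_specs or []
    for spec in effect_specs:
        if spec.factor_name not in factor_names:
            raise InvalidConfigError(f"unknown factor {spec.factor_name!r}")
    # distinct substream per generator stage so behavior and session noise
    # never share random draws
    rng = np.random.default_rng(
        [config.seed, 1] if seed is None else [seed, 1]
    )
    n = config.n_days
    data = {}
    for name in factor_names:
        x = _ar1(rng, n, config.ar_coefficient)
        x = (x - x.mean()) / x.std(ddof=1)
        data[name] = x
    index = pd.RangeIndex(n, name="day")
    truth = pd.DataFrame(data, index=index)
    table = truth.copy()
    if config.missing_fraction > 0:
        mask = rng.random(table.shape) < config.missing_fraction
        table = table.mask(mask)
    return SyntheticBehavior(table=table, truth=truth)


def _check_effect_links(effect_specs: list[EffectSpec], n_rois: int) -> None:
    used: set[int] = set()
    for spec in effect_specs:
        for i, j in spec.target_links:
            if not (0 <= i < n_rois and 0 <= j < n_rois):
                raise InvalidConfigError(f"link ({i},{j}) outside atlas of {n_rois} ROIs")
            if i in used or j in used:
                raise InvalidConfigError(
                    "effect-target ROIs must be disjoint across links"
                )
            used.update((i, j))


def gen_sessions(
    config: SynthConfig,
    atlas: pd.DataFrame,
    behavior: SyntheticBehavior,
    effect_specs: list[EffectSpec] | None = None,
    seed: int | None = None,
    task: str = "rest",
) -> tuple[list[SessionSeries], pd.DataFrame]:
    """Draw per-session ROI signals from a latent-factor model.

    Each community shares a latent signal; node i is
    sqrt(w) * g_community + sqrt(1-w) * noise with w = ``base_within``, so the
    baseline within-community correlation is ``base_within`` and every
    generating covariance matrix is positive semidefinite by construction.
    ROIs named in an :class:`EffectSpec` are detached from their community
    latent and share a pair latent whose loading tracks the behavioral factor
    at the configured lag (Fisher-z-linear coupling).

    Returns the sessions and a tidy ground-truth table with one row per
    (session_day, link) giving the generating correlation actually used.
    """
    effect_specs = effect_specs or []
    if len(atlas) != config.n_rois:
        raise InvalidConfigError("atlas length must match config.n_rois")
    _check_effect_links(effect_specs, config.n_rois)
    max_lag = max((s.lag_days for s in effect_specs), default=0)
    if config.session_days and config.session_days[0] - max_lag < 0:
        raise InvalidConfigError("behavior does not cover session_days minus max lag")
    rng = np.random.default_rng(
        [config.seed, 2] if seed is None else [seed, 2]
    )

    networks = atlas["network"].to_numpy()
    net_names, net_idx = np.unique(networks, return_inverse=True)

    sessions: list[SessionSeries] = []
    truth_rows = []
    w = config.base_within
    for day in config.session_days:
        T = config.n_time
        latents = rng.standard_normal((len(net_names), T))
        noise = rng.standard_normal((T, config.n_rois))
        data = np.sqrt(w) * latents[net_idx].T + np.sqrt(1 - w) * noise
        for spec in effect_specs:
            f = behavior.truth[spec.factor_name].loc[day - spec.lag_days]
            r = spec.generating_corr(f)
            if not -1 < r < 1:
                raise InvalidConfigError("generating correlation outside (-1, 1)")
            a = abs(r)
            for i, j in spec.target_links:
                # independent latent per link: only the targeted pair couples
                pair_latent = rng.standard_normal(T)
                ei = rng.standard_normal(T)
                ej = rng.standard_normal(T)
                data[:, i] = np.sqrt(a) * pair_latent + np.sqrt(1 - a) * ei
                sj = np.sign(r) if r != 0 else 1.0
                data[:, j] = sj * np.sqrt(a) * pair_latent + np.sqrt(1 - a) * ej
                truth_rows.append(
                    {
                        "session_day": day,
                        "roi_i": i,
                        "roi_j": j,
                        "factor": spec.factor_name,
                        "lag_days": spec.lag_days,
                        "generating_corr": r,
                    }
                )
        sessions.append(
            SessionSeries(data=data, tr_seconds=config.tr_seconds, task=task, session_day=day)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["session_day", "roi_i", "roi_j", "factor", "lag_days", "generating_corr"],
    )
    return sessions, truth


def gen_fd(
    config: SynthConfig,
    spike_prob: float = 0.05,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Framewise-displacement traces: quiet baseline plus occasional spikes.

    Baseline values stay strictly below the 0.2 mm censoring threshold; each
    volume independently becomes a spike (> 0.2 mm) with ``spike_prob``.
    """
    if not 0 <= spike_prob <= 1:
        raise InvalidConfigError("spike_prob must lie in [0, 1]")
    rng = np.random.default_rng(
        [config.seed, 3] if seed is None else [seed, 3]
    )
    out = []
    for _ in range(config.n_sessions):
        base = rng.uniform(0.01, 0.18, config.n_time)
        spikes = rng.random(config.n_time) < spike_prob
        fd = np.where(spikes, rng.uniform(0.25, 1.2, config.n_time), base)
        out.append(fd)
    return out


def gen_trials(
    n_trials: int,
    iti_range_seconds: tuple[float, float] = (2.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Trial onsets with inter-onset intervals uniform in the given range."""
    lo, hi = iti_range_seconds
    if lo <= 0 or hi < lo:
        raise InvalidConfigError("iti range must be positive and ordered")
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(lo, hi, max(n_trials, 0))
    onsets = np.cumsum(gaps)
    return pd.DataFrame({"trial": np.arange(n_trials), "onset_s": onsets[:n_trials]})


def write_dataset(
    out_dir: str | Path,
    config: SynthConfig,
    effect_specs: list[EffectSpec] | None = None,
    spike_prob: float = 0.05,
    task: str = "rest",
) -> Path:
    """Materialize a full synthetic dataset as plain TSV/JSON files.

    Layout: ``atlas.tsv``, ``behavior.tsv``, one ``sessions/day<d>.tsv`` per
    session (rows = volumes, columns = ROIs), ``fd/day<d>.tsv``, and
    ``truth.json`` holding the effect specs and realized generating values.
    """
    out = Path(out_dir)
    (out / "sessions").mkdir(parents=True, exist_ok=True)
    (out / "fd").mkdir(exist_ok=True)
    effect_specs = effect_specs or []
    atlas = gen_atlas(config.n_rois, config.n_networks, config.seed)
    behavior = gen_behavior(config, effect_specs)
    sessions, truth = gen_sessions(config, atlas, behavior, effect_specs, task=task)
    fds = gen_fd(config, spike_prob=spike_prob)

    atlas.to_csv(out / "atlas.tsv", sep="\t", index=False)
    behavior.table.to_csv(out / "behavior.tsv", sep="\t")
    behavior.truth.to_csv(out / "behavior_truth.tsv", sep="\t")
    for sess, fd in zip(sessions, fds):
        name = f"day{sess.session_day:03d}"
        pd.DataFrame(sess.data).to_csv(
            out / "sessions" / f"{name}.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame({"fd": fd}).to_csv(out / "fd" / f"{name}.tsv", sep="\t", index=False)
    meta = {
        "config": {k: v for k, v in asdict(config).items()},
        "task": task,
        "effects": [asdict(s) for s in effect_specs],
        "realized": truth.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=1))
    return out
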