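"""End-to-end orchestration with hypothesis presets.

Maps the study's eight preregistered hypotheses onto the library stages:
previous-day permutation regression on links and network metrics (H1-H3),
inter-day representational similarity (H4), lagged cross-correlation over
1-15 days (H5-H7), and time-segment classification accuracy maps (H8).
``run`` executes a configured analysis on a dataset directory written by
:func:`densefc.synth.write_dataset` (or any data in the same plain-TSV
layout) and writes tidy result tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import clean as cl
from . import connectivity as conn
from . import graphs, idrsa, lagcorr, permstats, segclass

__all__ = ["RunConfig", "preset", "run", "load_dataset"]

_SLEEP = ["total_sleep", "awake_time", "restless"]
_ACTIVITY = ["steps", "inactive_time"]
_ANS_MOOD = ["hrv_mean", "resp_mean", "naf_mean"]

#: Hypothesis presets: factors, networks, task, and analysis per Table of
#: preregistered hypotheses (sustained attention = pvt, working memory =
#: nback, movie = naturalistic viewing).
_PRESETS = {
    "H1": dict(
        task="pvt",
        analysis="regression",
        factors=list(_SLEEP),
        networks=["fronto_parietal", "default_mode", "somatomotor", "cingulo_opercular"],
    ),
    "H2": dict(
        task="nback",
        analysis="regression",
        factors=_SLEEP + _ACTIVITY,
        networks=["default_mode", "fronto_parietal", "somatomotor"],
    ),
    "H3": dict(
        task="rest",
        analysis="regression",
        factors=_SLEEP + _ANS_MOOD,
        covariates=["microsleep_pct"],
        networks=["default_mode", "fronto_parietal", "cingulo_opercular"],
    ),
    "H4": dict(
        task="movie",
        analysis="idrsa",
        factors=_SLEEP + _ANS_MOOD,
        networks=[],
    ),
    "H5": dict(
        task="pvt",
        analysis="lagcorr",
        factors=list(_SLEEP),
        networks=["fronto_parietal", "default_mode", "somatomotor", "cingulo_opercular"],
    ),
    "H6": dict(
        task="nback",
        analysis="lagcorr",
        factors=_SLEEP + _ACTIVITY,
        networks=["default_mode", "fronto_parietal", "somatomotor"],
    ),
    "H7": dict(
        task="rest",
        analysis="lagcorr",
        factors=_SLEEP + _ANS_MOOD,
        networks=["default_mode", "fronto_parietal", "cingulo_opercular"],
    ),
    "H8": dict(
        task="movie",
        analysis="segclass",
        factors=_SLEEP + _ANS_MOOD,
        networks=[],
    ),
}


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    data_dir: str
    out_dir: str
    analysis: str = "regression"        # regression | lagcorr | idrsa | segclass
    task: str = "rest"
    factors: list[str] = field(default_factory=lambda: list(_SLEEP))
    covariates: list[str] = field(default_factory=list)
    networks: list[str] = field(default_factory=lambda: ["default_mode"])
    densities: tuple[float, ...] = (0.10, 0.20, 0.30)
    fd_threshold: float = 0.2
    scrub: str = "ordinary"             # "ordinary" or "pct:<p>" (shared masks)
    n_perm: int = 10000
    seed: int = 0
    window: int = 25
    step: int = 1
    sg_window_seconds: float = 240.0

    def validate(self, behavior_columns) -> None:
        data = Path(self.data_dir)
        for sub in ("atlas.tsv", "behavior.tsv", "sessions"):
            if not (data / sub).exists():
                raise FileNotFoundError(f"config data_dir is missing {sub!r}")
        missing = [f for f in self.factors + self.covariates
                   if f not in behavior_columns]
        if missing:
            raise ValueError(f"factors absent from behavior table: {missing}")


def preset(hypothesis_id: str, data_dir: str, out_dir: str, **overrides) -> RunConfig:
    """RunConfig pre-populated for one of the hypotheses H1..H8."""
    try:
        base = dict(_PRESETS[hypothesis_id.upper()])
    except KeyError:
        raise KeyError(f"unknown hypothesis {hypothesis_id!r}; choose H1..H8") from None
    base.update(overrides)
    return RunConfig(data_dir=data_dir, out_dir=out_dir, **base)


def load_dataset(data_dir: str | Path):
    """Read the plain-TSV dataset layout into memory."""
    data = Path(data_dir)
    atlas = pd.read_csv(data / "atlas.tsv", sep="\t")
    behavior = pd.read_csv(data / "behavior.tsv", sep="\t", index_col="day")
    meta = {}
    if (data / "truth.json").exists():
        meta = json.loads((data / "truth.json").read_text())
    tr = meta.get("config", {}).get("tr_seconds", 0.594)
    sessions, fds, days = [], [], []
    for f in sorted((data / "sessions").glob("day*.tsv")):
        day = int(f.stem[3:])
        days.append(day)
        sessions.append(pd.read_csv(f, sep="\t").to_numpy(float))
        fd_file = data / "fd" / f.name
        fds.append(pd.read_csv(fd_file, sep="\t")["fd"].to_numpy(float)
                   if fd_file.exists() else np.zeros(sessions[-1].shape[0]))
    return atlas, behavior, sessions, fds, np.array(days), tr, meta


def _shared_mask(fds, cfg: RunConfig) -> cl.CensorMask:
    flags = np.stack([cl.flag_volumes(fd, cfg.fd_threshold) for fd in fds])
    if cfg.scrub == "ordinary":
        return cl.scrub_union(flags, cfg.fd_threshold)
    if cfg.scrub.startswith("pct:"):
        return cl.scrub_percentage(flags, float(cfg.scrub[4:]), cfg.fd_threshold)
    raise ValueError(f"unknown scrub rule {cfg.scrub!r}")


def run(config: RunConfig) -> Path:
    """Execute the configured analysis; returns the output directory.

    Writes ``metrics.tsv`` and the analysis result table (``regression.tsv``,
    ``lagcorr.tsv``, ``idrsa.tsv`` or ``segclass.tsv``) plus ``manifest.json``
    recording the config, seed and a hash of every output, so a rerun with
    the same config and seed reproduces the numbers exactly.
    """
    atlas, behavior, raw_sessions, fds, days, tr, _ = load_dataset(config.data_dir)
    config.validate(behavior.columns)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    behavior = behavior.apply(beh.impute_mean)
    cleaned = [
        cl.clean_session(s, tr, window_seconds=config.sg_window_seconds)
        for s in raw_sessions
    ]
    mask = _shared_mask(fds, config)
    mean_fd = np.array([fd.mean() for fd in fds])

    outputs: dict[str, pd.DataFrame] = {}
    if config.analysis in ("regression", "lagcorr"):
        adjs = [
            conn.pearson_adjacency(s, keep=mask.keep, session_day=d, task=config.task)
            for s, d in zip(cleaned, days)
        ]
        zs = [conn.fisher(a) for a in adjs]
        adjs_r = conn.residualize_motion(zs, mean_fd)
        metrics = graphs.metric_series(adjs_r, atlas, config.networks, config.densities)
        outputs["metrics"] = metrics
        if config.analysis == "regression":
            outputs["regression_links"] = permstats.model_links(
                [conn.fisher(a) for a in adjs_r], atlas, behavior,
                config.factors, config.networks, covariates=config.covariates,
                n_perm=config.n_perm, seed=config.seed,
            )
            outputs["regression"] = permstats.model_metrics(
                metrics, behavior, config.factors, covariates=config.covariates,
                n_perm=config.n_perm, seed=config.seed,
            )
        else:
            outputs["lagcorr"] = lagcorr.lag_analysis(
                metrics, behavior, config.factors, config.networks,
                threshold=config.densities[0],
                n_surr=config.n_perm, seed=config.seed,
            )
    elif config.analysis == "idrsa":
        prev_day = permstats.align_previous_day(days, behavior, config.factors)
        frames = []
        for factor in config.factors:
            res = idrsa.idrsa_analysis(
                cleaned, prev_day[factor].to_numpy(), mask.keep,
                n_perm=config.n_perm, seed=config.seed,
            )
            res["factor"] = factor
            frames.append(res)
        outputs["idrsa"] = pd.concat(frames, ignore_index=True)
    elif config.analysis == "segclass":
        units = [np.array([i]) for i in range(atlas.shape[0])]
        acc = segclass.accuracy_map(
            cleaned, units, window=config.window, step=config.step, keep=mask.keep
        )
        outputs["accuracy"] = acc
        outputs["segclass"] = segclass.accuracy_regression(
            acc, days, behavior, config.factors,
            n_perm=config.n_perm, seed=config.seed,
        )
    else:
        raise ValueError(f"unknown analysis {config.analysis!r}")

    hashes = {}
    for name, table in outputs.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_sessions": len(raw_sessions),
        "censored_volumes": mask.n_censored,
        "output_sha256": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
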