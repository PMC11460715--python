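import numpy as np
import pandas as pd
import pytest

from densefc import synth


@pytest.fixture(scope="session")
def small_atlas():
    """20 ROIs over 4 networks (5 nodes each)."""
    return synth.gen_atlas(20, 4, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(
        n_sessions=10,
        n_days=60,
        session_days=synth.default_session_days(10, start_day=16),
        n_rois=20,
        n_networks=4,
        n_time=120,
        tr_seconds=0.594,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_behavior(small_config):
    return synth.gen_behavior(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A written-out synthetic dataset small enough for pipeline smoke tests."""
    out = tmp_path_factory.mktemp("ds")
    cfg = synth.SynthConfig(
        n_sessions=8,
        n_days=60,
        session_days=synth.default_session_days(8, start_day=16),
        n_rois=12,
        n_networks=4,
        n_time=100,
        tr_seconds=0.594,
        missing_fraction=0.05,
        seed=7,
    )
    eff = synth.EffectSpec(
        target_links=[(0, 4)], factor_name="total_sleep", lag_days=1, slope=0.5
    )
    return synth.write_dataset(out, cfg, [eff], spike_prob=0.03), cfg
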