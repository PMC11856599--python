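"""Shared fixtures.

The parameter-recovery experiment (200 participants x 36 items, 4 chains x
5,000 iterations) is expensive, so it is computed once per session and shared
by every test that needs a fitted posterior on model-simulated data.
"""

from __future__ import annotations

import numpy as np
import pytest

import gazestrat as gs
from gazestrat.forest import ForestConfig, LabeledTable
from gazestrat.metrics import FEATURE_ORDER
from gazestrat.simulate import MetricProfiles, SimConfig, StrategyProfile


@pytest.fixture(scope="session")
def recovery_config() -> SimConfig:
    """Study-scale design with the default well-separated metric profiles."""
    return SimConfig(seed=20, n_participants=200, n_items=36)


@pytest.fixture(scope="session")
def recovery_data(recovery_config):
    truth = gs.simulate.generate_truth(recovery_config)
    features = gs.simulate.simulate_features(truth, recovery_config)
    return truth, features


@pytest.fixture(scope="session")
def recovery_posterior(recovery_data):
    """MEM fit on model-simulated data at full sampler settings."""
    _, features = recovery_data
    data = gs.mem.MemData.from_features(features)
    return gs.mem.fit(
        data, gs.mem.SamplerConfig(chains=4, iterations=5000, seed=3)
    )


@pytest.fixture(scope="session")
def planted_config() -> SimConfig:
    """Signal planted only in PTM/RLT/LFT; RT, NOT, ROT and RA are noise.

    Identical RT and toggle-count profiles across strategies remove the
    signal from rt/not/rot, zero sensitivity removes it from ra, and a
    strategy choice decoupled from ability/difficulty removes the indirect
    route through theta and b.
    """
    shared_rt = (float(np.log(22.0)), 0.35)
    return SimConfig(
        seed=42,
        n_participants=100,
        n_items=36,
        sensitivity_scale=0.0,
        strategy_link=(0.0, 0.0, 0.0),
        metric_profiles=MetricProfiles(
            cm=StrategyProfile(ptm=(16, 4), rlt_frac=(8, 2), rt=shared_rt, not_rate=5.0),
            re=StrategyProfile(ptm=(6, 9), rlt_frac=(2, 6), rt=shared_rt, not_rate=5.0),
        ),
    )


@pytest.fixture(scope="session")
def planted_table(planted_config) -> LabeledTable:
    truth = gs.simulate.generate_truth(planted_config)
    features = gs.simulate.simulate_features(truth, planted_config)
    X = features[list(FEATURE_ORDER)].to_numpy(dtype=float)
    return LabeledTable(X=X, y=truth.strategy.ravel(), feature_names=FEATURE_ORDER)


@pytest.fixture()
def forest_config() -> ForestConfig:
    return ForestConfig(n_trees=100, seed=1)
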