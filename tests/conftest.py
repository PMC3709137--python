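"""Shared fixtures: small trained models and synthetic sensor data.

Training fixtures are session-scoped because STDP training dominates test
runtime; the epoch budgets are reduced (stability is reached within a handful
of epochs at the default drive, see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pytest

import mgcsim as m
from mgcsim.pipelines import sensor_and_model_trajectories

TRAIN_SEEDS = (0, 1, 2, 3, 4)

#: angular directions (degrees from the ORN-1 axis) of the nonzero training ratios
TRAINED_DIRECTIONS = sorted(
    {
        float(np.degrees(np.arctan2(b, a)))
        for a, b in m.stimulus.TRAIN_AMPLITUDE_PAIRS
        if (a, b) != (0.0, 0.0)
    }
)


@pytest.fixture(scope="session")
def lca_model():
    return m.MGCModel(m.MGCConfig.lca(), seed=0)


@pytest.fixture(scope="session")
def trained_results(lca_model):
    """STDP training runs at the default drive for five connectome seeds."""
    out = []
    for seed in TRAIN_SEEDS:
        model = m.MGCModel(m.MGCConfig.lca(), seed=seed)
        out.append(model.fit(m.RatioTrainSpec(), epochs=40, seed=seed))
    return out


@pytest.fixture(scope="session")
def surviving_results():
    """Training in the surviving-LN regime (stronger afferent pulse gain)."""
    cfg = m.MGCConfig.lca(g_orn_ln=2.0, g_ln_ln=0.5)
    model = m.MGCModel(cfg, seed=0)
    return model.fit(m.RatioTrainSpec(), epochs=60, seed=0)


@pytest.fixture(scope="session")
def sawr_traces():
    spec = m.SAWRSyntheticSpec(trials_per_class=5)
    return m.make_synthetic_sawr(spec, seed=7)


@pytest.fixture(scope="session")
def sensor_trajectory_sets(sawr_traces):
    """(normalised raw, model output) trajectory sets for one sensor-matched net."""
    conn = m.build_mgc(m.MGCConfig.sensor_matched(), seed=0)
    return sensor_and_model_trajectories(conn, sawr_traces, seed=3)
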