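"""Shared fixtures: all data is generated programmatically at test time.

Model training is slow relative to a unit test, so trained models and
calibrated thresholds are session-scoped and shared across test modules;
tests must not mutate them.
"""

import numpy as np
import pytest

from rriguard.aed import (
    DetectionThresholds,
    calibrate_re_threshold,
    calibrate_rri_limits,
)
from rriguard.daem import train_dae_pair
from rriguard.neuralnet import AEModel, TrainConfig, train
from rriguard.rri_data import build_hankel
from rriguard.synthgen import simulate_normal_rri


@pytest.fixture(scope="session")
def train_series():
    return simulate_normal_rri(3000, seed=10)


@pytest.fixture(scope="session")
def validation_series():
    return simulate_normal_rri(12000, seed=11)


@pytest.fixture(scope="session")
def ae_model(train_series):
    rows = build_hankel(train_series).rows
    X = rows - rows.mean(axis=1, keepdims=True)
    return train(X, X, role="AE", cfg=TrainConfig(seed=1))


@pytest.fixture(scope="session")
def thresholds(ae_model, validation_series):
    r1, r2 = calibrate_rri_limits(validation_series)
    return DetectionThresholds(
        re_max=calibrate_re_threshold(ae_model, validation_series), r1=r1, r2=r2
    )


@pytest.fixture(scope="session")
def dae_models():
    series = simulate_normal_rri(3000, seed=12)
    return {
        f"DAE_{ty}": train_dae_pair(series, ty, cfg=TrainConfig(seed=2), n_events=800)
        for ty in ("PVC", "PAC")
    }


@pytest.fixture
def zero_model():
    """All-zero weights: reconstruction is 0, so RE = ||centered window||."""
    return AEModel(
        W1=np.zeros((3, 4)),
        b1=np.zeros(3),
        W2=np.zeros((4, 3)),
        b2=np.zeros(4),
        hidden_activation="sigmoid",
        role="AE",
    )
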