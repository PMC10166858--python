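"""Shared fixtures.

The "study" fixtures reproduce the package's default synthetic experiment:
a five-regime, ~8,000-step, 10-channel recording (seed 0) with a
convolutional autoencoder trained on per-regime clips (seed 100).  They are
session-scoped because training takes a couple of minutes and several
end-to-end tests share the model.
"""

from __future__ import annotations

import numpy as np
import pytest

from lsuss import (TimeSeries, TrainingConfig, build_autoencoder,
                   generate_discontinuous_training_set, train_autoencoder)
from lsuss.synthetic import (EMG_LIKE_NOISE_SD, emg_like_dataset,
                             emg_like_regimes)

STUDY_SEED = 0          # pinned fixture seed for the end-to-end study
STUDY_NW = 32
STUDY_TC = 1600         # ~ expected segment length


@pytest.fixture(scope="session")
def emg_dataset():
    return emg_like_dataset(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_model():
    """Convolutional autoencoder trained on discontinuous per-regime clips
    (the artificial-training-set construction), deterministic."""
    clips = generate_discontinuous_training_set(
        emg_like_regimes(), reps=2, nc=10, n_sources=3,
        noise_sd=EMG_LIKE_NOISE_SD, n_noise_channels=2, seed=100)
    spec = build_autoencoder("convolutional", 10, STUDY_NW)
    cfg = TrainingConfig(seed=STUDY_SEED, train_stride=4, max_epochs=80,
                         patience=15)
    model, _ = train_autoencoder(spec, clips, cfg)
    return model


@pytest.fixture(scope="module")
def tiny_model():
    """A small fully connected autoencoder trained in a few seconds, for
    tests that need *a* trained model rather than a good one."""
    rng = np.random.default_rng(7)
    t = np.arange(1200)
    src = np.stack([np.sin(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.11 * t)])
    mix = rng.normal(size=(4, 2))
    ts = TimeSeries((mix @ src).T + 0.05 * rng.normal(size=(1200, 4)))
    spec = build_autoencoder("fully_connected", 4, 16)
    cfg = TrainingConfig(seed=1, train_stride=4, max_epochs=30, patience=10)
    model, _ = train_autoencoder(spec, ts, cfg)
    return model
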