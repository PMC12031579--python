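"""Shared fixtures. The expensive trained-model and cross-validation
fixtures are session-scoped so several tests can interrogate one run."""

from __future__ import annotations

import numpy as np
import pytest

from cqtnet import (
    SimParams,
    TrainConfig,
    build_dataset,
    build_model,
    cross_validate,
    simulate_dataset,
    train,
)

#: Strongly separable study conditions for the recovery surrogate: large
#: relevant/comparison contrast, low noise.
SEPARABLE = dict(effect_size=3.0, noise_sd=0.1, drift_sd=0.05)

#: Reduced training schedule used for cross-validation at test scale.
REDUCED_EPOCHS = TrainConfig(max_epochs=4, validation_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def small_chart_params() -> SimParams:
    return SimParams(**SEPARABLE)


@pytest.fixture(scope="session")
def tiny_dataset():
    """6 series / 54 question sets, separable; for fast end-to-end checks."""
    params = SimParams(**SEPARABLE)
    recordings, manifests = simulate_dataset(3, 3, params, seed=9)
    return build_dataset(recordings, manifests), manifests


@pytest.fixture(scope="session")
def trained_separable():
    """Model trained 30 epochs on 64 noiseless separable segments, plus the
    held-out remainder (8 segments of a 72-segment dataset)."""
    params = SimParams(effect_size=3.0, noise_sd=0.0, drift_sd=0.0)
    recordings, manifests = simulate_dataset(4, 4, params, seed=11)
    segments = build_dataset(recordings, manifests)
    train_segs, held_out = segments[:64], segments[64:]
    model = build_model(seed=1)
    fitted = train(
        model, train_segs,
        TrainConfig(max_epochs=30, validation_fraction=0.0, seed=2),
    )
    return fitted, train_segs, held_out


def _cv_dataset(effect_size: float):
    params = SimParams(**{**SEPARABLE, "effect_size": effect_size})
    recordings, manifests = simulate_dataset(12, 12, params, seed=5)
    return build_dataset(recordings, manifests), manifests


@pytest.fixture(scope="session")
def cv_separable():
    """10-fold CV on 24 separable series (reduced epochs)."""
    segments, manifests = _cv_dataset(3.0)
    return cross_validate(
        segments, manifests, train_config=REDUCED_EPOCHS, k=10,
        unit="series", seed=5,
    )


@pytest.fixture(scope="session")
def cv_null():
    """10-fold CV on 24 series with zero effect size (no signal)."""
    segments, manifests = _cv_dataset(0.0)
    return cross_validate(
        segments, manifests, train_config=REDUCED_EPOCHS, k=10,
        unit="series", seed=5,
    )
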