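"""Shared fixtures.

The "benchmark" fixtures reproduce the standard synthetic evaluation
setup (50 train + 50 test clips per class, 1 px jitter, 2% landmark
dropout, seed 0).  They are session-scoped because simulating the data
and training the two streams is the expensive part of the suite; every
test that uses them sees the same immutable objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitstream.core import ActionLabel, SkeletonSchema
from gaitstream.io import RunConfig
from gaitstream.synthetic import make_dataset

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def schema() -> SkeletonSchema:
    return SkeletonSchema()


@pytest.fixture(scope="session")
def benchmark_config() -> RunConfig:
    return RunConfig(
        seed=BENCHMARK_SEED,
        n_per_class=100,
        split=0.5,
        jitter_sd=1.0,
        invalid_prob=0.02,
    )


@pytest.fixture(scope="session")
def benchmark_data(benchmark_config):
    """50 train + 50 test clips per class at default gait parameters."""
    return make_dataset(
        n_per_class=benchmark_config.n_per_class,
        split=benchmark_config.split,
        seed=benchmark_config.seed,
        jitter_sd=benchmark_config.jitter_sd,
        invalid_prob=benchmark_config.invalid_prob,
    )


@pytest.fixture(scope="session")
def skeleton_model(benchmark_data, benchmark_config):
    from gaitstream.pipeline import train_skeleton_stream

    train, _ = benchmark_data
    return train_skeleton_stream(train, benchmark_config)


@pytest.fixture(scope="session")
def outline_model(benchmark_data, benchmark_config):
    from gaitstream.pipeline import train_outline_stream

    train, _ = benchmark_data
    return train_outline_stream(train, benchmark_config)


@pytest.fixture(scope="session")
def benchmark_predictions(benchmark_data, benchmark_config, skeleton_model, outline_model):
    """(train_preds, test_preds) where each is (yp, ys, labels)."""
    from gaitstream.pipeline import predict_streams

    train, test = benchmark_data
    tr = predict_streams(train, outline_model, skeleton_model, benchmark_config)
    te = predict_streams(test, outline_model, skeleton_model, benchmark_config)
    return tr, te
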