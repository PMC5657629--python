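"""Shared fixtures: topology, configs, and the cross-subject benchmark.

The benchmark (5 classes including a direction-reversed pair, 8 subjects,
2 sequences per class and subject, odd subjects train) is expensive enough
to build once per session and share across the recognition, evaluation and
acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from kinaction.config import PipelineConfig
from kinaction.evaluation import evaluate_segmented
from kinaction.regularization import TrainingIndex, fit_training_index
from kinaction.synthetic import generate_dataset, make_topology

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def topology():
    return make_topology()


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def benchmark_dataset():
    return generate_dataset(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_split(benchmark_dataset):
    return benchmark_dataset.split_odd_even()


@pytest.fixture(scope="session")
def benchmark_index(benchmark_split) -> TrainingIndex:
    train, _ = benchmark_split
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_training_index(train, PipelineConfig())


@pytest.fixture(scope="session")
def benchmark_segmented(benchmark_index, benchmark_split):
    _, test = benchmark_split
    return evaluate_segmented(benchmark_index, test, PipelineConfig())


def make_toy_index(
    n: int = 60,
    dim: int = 10,
    n_classes: int = 3,
    n_seqs: int = 12,
    seed: int = 0,
    grid: float | None = None,
) -> TrainingIndex:
    """A small random TrainingIndex for KNN/confidence unit tests.

    ``grid`` snaps coordinates to multiples of it so exact distance ties
    occur and the deterministic tie-break is exercised.
    """
    rng = np.random.default_rng(seed)
    vectors = rng.normal(size=(n, dim))
    if grid:
        vectors = np.round(vectors / grid) * grid
    classes = tuple(chr(ord("a") + i) for i in range(n_classes))
    source_ids = tuple(f"seq{i:02d}" for i in range(n_seqs))
    return TrainingIndex(
        vectors=vectors,
        class_codes=rng.integers(0, n_classes, n),
        time_labels=rng.integers(0, 30, n),
        seq_codes=rng.integers(0, n_seqs, n),
        classes=classes,
        source_ids=source_ids,
    )
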