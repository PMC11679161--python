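"""Shared fixtures: small synthetic datasets and records, all seeded."""

import numpy as np
import pytest

from mbtcn.preprocess import BeatMatrix
from mbtcn.synthetic import GeneratorConfig, generate_dataset

#: The published fold-1 confusion matrix of the five-class benchmark
#: (rows = true N,S,V,F,Q; columns = predicted), used as reference input.
FOLD1_CONFUSION = np.array([
    [3052, 11, 8, 1, 2],
    [4, 520, 5, 1, 2],
    [4, 6, 1373, 5, 3],
    [0, 2, 7, 148, 0],
    [1, 0, 1, 3, 1567],
], dtype=np.int64)


@pytest.fixture(scope="session")
def fold1_confusion() -> np.ndarray:
    return FOLD1_CONFUSION.copy()


@pytest.fixture(scope="session")
def clean_generator() -> GeneratorConfig:
    """Noise- and jitter-free generator (pure class templates)."""
    return GeneratorConfig(seed=7).noiseless()


@pytest.fixture(scope="session")
def small_balanced_beats() -> BeatMatrix:
    """600 lightly noisy beats with equal-ish class proportions."""
    cfg = GeneratorConfig(seed=11,
                          class_proportions=(0.2, 0.2, 0.2, 0.2, 0.2))
    return generate_dataset(cfg, n=600)


@pytest.fixture(scope="session")
def imbalanced_beats() -> BeatMatrix:
    """1200 beats at the default imbalanced proportions."""
    return generate_dataset(GeneratorConfig(seed=13), n=1200)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
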