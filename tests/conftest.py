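"""Shared fixtures.

Expensive synthetic datasets and their feature matrices are session-scoped so
the classification tests and the acceptance suite reuse one featurization.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegattn import featurize_dataset, generate_labeled_dataset
from eegattn.synth import SignalSpec

FS = 512


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tone(freq: float, n: int = 512, fs: float = FS, phase: float = 0.0) -> np.ndarray:
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def shifted_dataset():
    """40 windows/class with a 4x alpha-amplitude shift between classes."""
    return generate_labeled_dataset(
        {"concentration": 40, "immersion": 40},
        base_spec=SignalSpec(),
        class_shift={"alpha": 4.0},
        window_seconds=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def shifted_features(shifted_dataset):
    return featurize_dataset(shifted_dataset, "proposed")


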