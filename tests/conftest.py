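"""Shared fixtures: synthetic cohorts and separable feature matrices."""

from __future__ import annotations

import numpy as np
import pytest

from ramanscreen.spectrum import CLASS_LABELS
from ramanscreen.synth import CohortConfig, simulate_cohort
from ramanscreen.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort: 8/6/7 samples, 3 scans each."""
    config = CohortConfig(
        n_cancer=8, n_benign=6, n_normal=7, scans_per_sample=3, seed=42
    )
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Preprocessed feature matrix of the small cohort."""
    _, cohort, _ = small_cohort
    return preprocess_cohort(cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort: 129/91/113 samples, 10 scans each."""
    config = CohortConfig(seed=101)
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Preprocessed features of the full cohort (333 x 1201)."""
    _, cohort, _ = default_cohort
    return preprocess_cohort(cohort)


def make_blob_features(
    n_per_class: int = 20,
    n_channels: int = 30,
    separation: float = 4.0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Three Gaussian blobs in channel space, one per class label."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(3, n_channels))
    rows, labels = [], []
    for c, cls in enumerate(CLASS_LABELS):
        rows.append(centers[c] + rng.normal(0.0, noise_sd, size=(n_per_class, n_channels)))
        labels.extend([cls] * n_per_class)
    return np.vstack(rows), np.array(labels)
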