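"""Shared fixtures: random SPD factories and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from riemecg import cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rand_spd(rng):
    """Factory for random well-conditioned SPD matrices."""

    def make(n: int, scale: float = 1.0) -> np.ndarray:
        a = rng.standard_normal((n, n))
        return scale * (a @ a.T + n * np.eye(n))

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3-class cohort (5 s records) reused across ingestion tests."""
    cfg = cohort.CohortConfig(
        n_classes=3,
        patients_per_class=(4, 3, 3),
        ecg=cohort.EcgSimConfig(duration_s=5.0),
        seed=77,
    )
    return cohort.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return cohort.to_dataset(small_cohort)
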