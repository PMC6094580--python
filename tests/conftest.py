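from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actisig.accel import EpochStream
from actisig.metabolic import (
    adjust_outcomes,
    composite_score,
    derive_indices,
    validate_panel,
)
from actisig.simulate import CohortConfig, simulate_cohort


def make_stream(
    counts,
    epoch_length: int = 10,
    start: str = "2024-05-06 06:00:00",
    subject_id: str = "T1",
) -> EpochStream:
    counts = np.asarray(counts)
    times = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(len(counts)) * epoch_length, unit="s"
    )
    return EpochStream(
        subject_id=subject_id,
        times=pd.DatetimeIndex(times),
        counts=counts,
        epoch_length=epoch_length,
    )


def cohort_xy(n_subjects: int = 300, seed: int = 0):
    """Simulated cohort run through the real outcome pipeline -> (X, y, labels)."""
    cohort = simulate_cohort(CohortConfig(n_subjects=n_subjects), seed=seed)
    valid, _ = validate_panel(cohort.panel)
    derived = derive_indices(valid)
    adjusted = adjust_outcomes(derived)
    y = composite_score(adjusted)
    X = cohort.features.loc[valid["subject_id"]].to_numpy(dtype=float)
    return X, y, cohort.bin_labels


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-size cohort shared across read-only tests."""
    X, y, labels = cohort_xy(n_subjects=300, seed=42)
    return X, y, labels
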