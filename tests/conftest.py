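from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexscreen.cohort_io import ExpressionCohort


def make_cohort(
    values,
    features=None,
    samples=None,
    cohort_id="c1",
    group_id="g1",
) -> ExpressionCohort:
    """Build a cohort from a nested list / array (features x samples)."""
    arr = np.asarray(values, dtype=float)
    if features is None:
        features = [f"gene{i}" for i in range(arr.shape[0])]
    if samples is None:
        samples = [f"s{j + 1}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=features, columns=samples)
    return ExpressionCohort(cohort_id, group_id, frame)


@pytest.fixture
def small_cohort() -> ExpressionCohort:
    rng = np.random.default_rng(42)
    values = rng.normal(7, 1, size=(10, 8))
    return make_cohort(values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
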