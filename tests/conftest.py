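import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ppi_flutter.interval_data import (  # noqa: E402
    Cohort,
    IntervalSeries,
    Mechanism,
    Provenance,
    Technique,
)


@pytest.fixture
def fafl_series() -> IntervalSeries:
    return IntervalSeries(
        "F01", Mechanism.FAFL, np.array([200.0, 215.0, 190.0, 225.0, 205.0, 210.0])
    )


@pytest.fixture
def small_cohort() -> Cohort:
    """Two FAFL and four MAFL original records with distinct interval patterns."""
    rng = np.random.default_rng(99)
    series = [
        IntervalSeries(f"F{i:02d}", Mechanism.FAFL, 230 + 12 * rng.standard_normal(30))
        for i in range(2)
    ] + [
        IntervalSeries(f"M{i:02d}", Mechanism.MAFL, 248 + 3 * rng.standard_normal(30))
        for i in range(4)
    ]
    return Cohort(tuple(series), name="small")


@pytest.fixture
def feature_frame_factory():
    """Build a feature-matrix-shaped frame from a plain (X, labels) pair."""

    def make(X: np.ndarray, labels, provenance=None, source=None) -> pd.DataFrame:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
        df.insert(0, "record_id", [f"R{i:03d}" for i in range(n)])
        df.insert(1, "mechanism", list(labels))
        df.insert(2, "provenance", provenance if provenance is not None else ["original"] * n)
        df.insert(3, "technique", ["none"] * n)
        df.insert(4, "source_record_id", source if source is not None else [""] * n)
        return df

    return make
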