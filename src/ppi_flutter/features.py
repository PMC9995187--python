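"""Descriptive-statistics features of an interval series.

Ten order-insensitive statistics summarise each record's P-P intervals in four
groups -- central tendency (mean, median, mode), dispersion (standard
deviation, variance), shape (skewness, kurtosis) and length/extremes
(maximum, minimum, sum).  Estimator choices, since the statistics alone do
not pin them down:

* variance and standard deviation use the sample (``n - 1``) form;
* skewness is the adjusted Fisher-Pearson sample skewness (population form
  at ``n = 2``, where the adjustment is undefined);
* kurtosis is the Pearson, non-excess population moment ratio ``m4 / m2^2``
  (3 for a normal distribution), defined for every ``n >= 2``;
* the mode of continuous durations is taken after rounding to the nearest
  millisecond, ties broken toward the smallest value.

A constant series has zero variance, where skewness and kurtosis are
undefined; both are reported as 0 with ``degenerate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ppi_flutter.interval_data import Cohort, IntervalSeries, Mechanism, ValidationError

FEATURE_COLUMNS = [
    "F1_mean",
    "F2_median",
    "F3_mode",
    "F4_std",
    "F5_variance",
    "F6_skewness",
    "F7_kurtosis",
    "F8_maximum",
    "F9_minimum",
    "F10_sum",
]

META_COLUMNS = ["record_id", "mechanism", "provenance", "technique", "source_record_id"]


@dataclass(frozen=True)
class FeatureVector:
    """The ten descriptive statistics of one series (ms-based units)."""

    record_id: str
    mechanism: Mechanism
    F1_mean: float
    F2_median: float
    F3_mode: float
    F4_std: float
    F5_variance: float
    F6_skewness: float
    F7_kurtosis: float
    F8_maximum: float
    F9_minimum: float
    F10_sum: float
    degenerate: bool = False

    def values(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


def _mode_nearest_ms(x: np.ndarray) -> float:
    # round half away from zero to the nearest 1 ms; intervals are positive
    rounded = np.floor(x + 0.5)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])  # unique() sorts: first max = smallest


def extract_features(series: IntervalSeries) -> FeatureVector:
    """Compute the 10-feature vector of one series (requires >= 2 intervals)."""
    x = np.asarray(series.intervals, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError(
            f"record {series.record_id!r}: need >= 2 intervals for features, got {n}"
        )
    degenerate = bool(np.ptp(x) == 0)
    if degenerate:
        skew = kurt = 0.0
        var = std = 0.0
    else:
        var = float(np.var(x, ddof=1))
        std = float(np.sqrt(var))
        skew = float(stats.skew(x, bias=(n < 3)))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return FeatureVector(
        record_id=series.record_id,
        mechanism=series.mechanism,
        F1_mean=float(np.mean(x)),
        F2_median=float(np.median(x)),
        F3_mode=_mode_nearest_ms(x),
        F4_std=std,
        F5_variance=var,
        F6_skewness=skew,
        F7_kurtosis=kurt,
        F8_maximum=float(np.max(x)),
        F9_minimum=float(np.min(x)),
        F10_sum=float(np.sum(x)),
        degenerate=degenerate,
    )


def build_feature_matrix(cohort: Cohort) -> pd.DataFrame:
    """Feature matrix with one row per series, in cohort order.

    Columns: record metadata (id, mechanism, provenance, technique, source)
    followed by the fixed F1..F10 feature columns.  The metadata is retained
    so downstream cross-validation can group synthetic series with their
    source records.
    """
    rows = []
    for s in cohort:
        fv = extract_features(s)
        row = {
            "record_id": s.record_id,
            "mechanism": s.mechanism.value,
            "provenance": s.provenance.value,
            "technique": s.technique.value,
            "source_record_id": s.source_record_id,
        }
        row.update({c: getattr(fv, c) for c in FEATURE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
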