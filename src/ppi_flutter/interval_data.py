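"""Domain types and I/O for labelled P-to-P interval series.

An :class:`IntervalSeries` is one ECG record's ordered sequence of intervals
between consecutive atrial (P-wave) peaks, in milliseconds, together with the
mechanism label and -- for oversampled series -- provenance bookkeeping.  A
:class:`Cohort` is a collection of such series with unique record ids.

Intervals longer than 300 ms are considered artefacts of missed peaks rather
than true consecutive P-P intervals and are dropped by
:func:`filter_intervals`.  The boundary is read strictly: exactly 300 ms is
kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Longest plausible interval between truly consecutive P-waves (ms).
MAX_INTERVAL_MS = 300.0

_CSV_COLUMNS = [
    "record_id",
    "mechanism",
    "interval_ms",
    "provenance",
    "technique",
    "source_record_id",
]


class ValidationError(ValueError):
    """Raised when domain invariants or file contents are invalid."""


class Mechanism(str, Enum):
    """Atrial-flutter mechanism: focal (point source) vs macroreentrant loop."""

    FAFL = "FAFL"
    MAFL = "MAFL"


class Provenance(str, Enum):
    ORIGINAL = "original"
    SYNTHETIC = "synthetic"


class Technique(str, Enum):
    """Oversampling technique a synthetic series was generated with."""

    NONE = "none"
    SMOTE = "smote"
    MODIFIED_SMOTE = "modified_smote"
    SMOOTHED_BOOTSTRAP = "smoothed_bootstrap"


@dataclass(frozen=True, eq=False)
class IntervalSeries:
    """One record's ordered P-P intervals (ms) plus label and provenance.

    Invariants enforced at construction:

    * intervals are finite; original series must be strictly positive
      (synthetic series may carry out-of-range extrapolations by design),
    * ``provenance == SYNTHETIC`` iff ``technique != NONE`` iff
      ``source_record_id`` is non-empty.
    """

    record_id: str
    mechanism: Mechanism
    intervals: np.ndarray
    provenance: Provenance = Provenance.ORIGINAL
    technique: Technique = Technique.NONE
    source_record_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))
        object.__setattr__(self, "provenance", Provenance(self.provenance))
        object.__setattr__(self, "technique", Technique(self.technique))
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValidationError(
                f"record {self.record_id!r}: intervals must be one-dimensional"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"record {self.record_id!r}: non-finite interval")
        if self.provenance is Provenance.ORIGINAL and arr.size and np.min(arr) <= 0:
            raise ValidationError(
                f"record {self.record_id!r}: original intervals must be > 0 ms"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "intervals", arr)

        is_synth = self.provenance is Provenance.SYNTHETIC
        if is_synth != (self.technique is not Technique.NONE) or is_synth != bool(
            self.source_record_id
        ):
            raise ValidationError(
                f"record {self.record_id!r}: provenance, technique and "
                "source_record_id must be jointly original or jointly synthetic"
            )

    def __len__(self) -> int:
        return int(self.intervals.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSeries):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.mechanism is other.mechanism
            and self.provenance is other.provenance
            and self.technique is other.technique
            and self.source_record_id == other.source_record_id
            and np.array_equal(self.intervals, other.intervals)
        )

    def __hash__(self) -> int:
        return hash((self.record_id, self.mechanism, self.intervals.tobytes()))


def filter_intervals(
    series: IntervalSeries, max_interval: float = MAX_INTERVAL_MS
) -> IntervalSeries:
    """Drop intervals strictly above ``max_interval`` ms, preserving order.

    Idempotent; metadata is unchanged.  An empty result is legal.
    """
    if max_interval <= 0:
        raise ValidationError("max_interval must be > 0")
    kept = series.intervals[series.intervals <= max_interval]
    return replace(series, intervals=kept)


def peaks_to_intervals(peak_times: Sequence[float]) -> np.ndarray:
    """First differences of strictly increasing peak timestamps (ms).

    Plumbing between an upstream peak detector and the interval-series
    representation; a single peak yields an empty interval sequence.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size >= 2 and np.min(np.diff(t)) <= 0:
        raise ValidationError("peak_times must be strictly increasing")
    return np.diff(t)


@dataclass(frozen=True)
class Cohort:
    """A labelled collection of interval series with unique record ids."""

    series: tuple[IntervalSeries, ...]
    name: str = "cohort"

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.record_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[IntervalSeries]:
        return iter(self.series)

    def get(self, record_id: str) -> IntervalSeries:
        for s in self.series:
            if s.record_id == record_id:
                return s
        raise KeyError(record_id)

    def originals(self) -> tuple[IntervalSeries, ...]:
        return tuple(s for s in self.series if s.provenance is Provenance.ORIGINAL)

    def synthetics(self) -> tuple[IntervalSeries, ...]:
        return tuple(s for s in self.series if s.provenance is Provenance.SYNTHETIC)

    def class_counts(self, originals_only: bool = False) -> dict[Mechanism, int]:
        pool = self.originals() if originals_only else self.series
        counts = {m: 0 for m in Mechanism}
        for s in pool:
            counts[s.mechanism] += 1
        return counts

    @property
    def minority_mechanism(self) -> Mechanism:
        """Class with the fewest *original* records; FAFL on a tie."""
        counts = self.class_counts(originals_only=True)
        if counts[Mechanism.FAFL] <= counts[Mechanism.MAFL]:
            return Mechanism.FAFL
        return Mechanism.MAFL

    @property
    def imbalance_ratio(self) -> float:
        """Majority / minority record count (>= 1); inf if a class is absent."""
        counts = self.class_counts()
        lo, hi = sorted(counts.values())
        if lo == 0:
            return float("inf")
        return hi / lo

    def with_series(self, extra: Iterable[IntervalSeries], name: str | None = None) -> "Cohort":
        return Cohort(self.series + tuple(extra), name=name or self.name)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _series_to_dict(s: IntervalSeries) -> dict:
    return {
        "record_id": s.record_id,
        "mechanism": s.mechanism.value,
        "intervals": [float(v) for v in s.intervals],
        "provenance": s.provenance.value,
        "technique": s.technique.value,
        "source_record_id": s.source_record_id,
    }


def _series_from_dict(d: dict) -> IntervalSeries:
    try:
        mech = Mechanism(d["mechanism"])
    except ValueError as exc:
        raise ValidationError(
            f"record {d.get('record_id')!r}: unknown mechanism {d.get('mechanism')!r}"
        ) from exc
    return IntervalSeries(
        record_id=str(d["record_id"]),
        mechanism=mech,
        intervals=np.asarray(d["intervals"], dtype=float),
        provenance=Provenance(d.get("provenance", "original")),
        technique=Technique(d.get("technique", "none")),
        source_record_id=str(d.get("source_record_id", "")),
    )


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> None:
    """Write a cohort as long-format CSV (one row per interval) or JSON.

    CSV cannot represent a series with zero intervals; use JSON for those.
    Values are written at full precision so that ``read(write(c)) == c``.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = {"name": cohort.name, "series": [_series_to_dict(s) for s in cohort]}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return
    if fmt != "csv":
        raise ValidationError(f"unknown cohort format {fmt!r}")
    rows = []
    for s in cohort:
        if len(s) == 0:
            raise ValidationError(
                f"record {s.record_id!r} has no intervals; long-format CSV cannot "
                "represent it -- write JSON instead"
            )
        for v in s.intervals:
            rows.append(
                (
                    s.record_id,
                    s.mechanism.value,
                    repr(float(v)),
                    s.provenance.value,
                    s.technique.value,
                    s.source_record_id,
                )
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_cohort(path: str | Path, format: str | None = None, name: str | None = None) -> Cohort:
    """Read a cohort from CSV or JSON (see :func:`write_cohort` for layout).

    Raises :class:`ValidationError`, identifying the offending row, for unknown
    mechanism labels, non-numeric intervals, or a record id used with
    conflicting metadata.  An empty file yields an empty cohort.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        series = [_series_from_dict(d) for d in payload.get("series", [])]
        return Cohort(tuple(series), name=name or payload.get("name", path.stem))
    if fmt != "csv":
        raise ValidationError(f"unknown cohort format {fmt!r}")

    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return Cohort((), name=name or path.stem)
    if df.empty:
        return Cohort((), name=name or path.stem)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    order: list[str] = []
    meta: dict[str, tuple] = {}
    values: dict[str, list[float]] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rid = row.record_id
        if row.mechanism not in Mechanism._value2member_map_:
            raise ValidationError(
                f"{path} row {row_number}: unknown mechanism {row.mechanism!r}"
            )
        try:
            interval = float(row.interval_ms)
        except ValueError as exc:
            raise ValidationError(
                f"{path} row {row_number}: non-numeric interval {row.interval_ms!r}"
            ) from exc
        this_meta = (row.mechanism, row.provenance, row.technique, row.source_record_id)
        if rid not in meta:
            meta[rid] = this_meta
            values[rid] = []
            order.append(rid)
        elif meta[rid] != this_meta:
            raise ValidationError(
                f"{path} row {row_number}: record {rid!r} re-appears with "
                f"conflicting metadata {this_meta} != {meta[rid]}"
            )
        values[rid].append(interval)

    series = []
    for rid in order:
        mech, prov, tech, src = meta[rid]
        series.append(
            IntervalSeries(
                record_id=rid,
                mechanism=Mechanism(mech),
                intervals=np.asarray(values[rid], dtype=float),
                provenance=Provenance(prov),
                technique=Technique(tech),
                source_record_id=src,
            )
        )
    return Cohort(tuple(series), name=name or path.stem)
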