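"""Minority-class oversampling for interval series.

Three samplers generate synthetic P-P intervals from an original series:

* **SMOTE** -- linear interpolation between a randomly chosen anchor interval
  ``x_j`` and a neighbour ``x_k``:  ``s = x_j + a (x_k - x_j)`` with
  ``a ~ U(0, 1)``.  For i.i.d. data this construction preserves the mean but
  shrinks the variance to ``2/3`` of the original.
* **modified SMOTE** -- the same interpolation with the coefficient ``3/2``
  applied to ``a``: ``s = x_j + (3/2) a (x_k - x_j)``.  The factor is the
  unique positive solution of ``Var[(1 - c a) x_j + c a x_k] = Var[x]``
  (see :func:`solve_variance_coefficient`), so the synthetic variance matches
  the original.  The draw may extrapolate past the neighbour by up to half
  the segment length.
* **smoothed bootstrap** -- resampling with replacement plus a Gaussian
  kernel shift: ``s = x_j + h z``, ``z ~ N(0, 1)``, which renders the
  bootstrap distribution continuous.  Bandwidth ``h = 0`` degenerates to the
  classic bootstrap; by default ``h`` follows Silverman's rule.

The neighbourhood is the whole pool minus the anchor instance (``k = N - 1``
nearest neighbours), so no k-NN search is involved.  By default each record is
augmented from its own series; a pooled-minority neighbour mode is available.

Synthetic values falling outside ``(0, 300]`` ms are kept by default
(``bounds_policy = "none"``) because redrawing would break the moment
contracts above; a ``"redraw"`` policy is available and logs how often it
fired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ppi_flutter.interval_data import (
    Cohort,
    IntervalSeries,
    Provenance,
    Technique,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SAMPLER_TECHNIQUES = (
    Technique.SMOTE,
    Technique.MODIFIED_SMOTE,
    Technique.SMOOTHED_BOOTSTRAP,
)

#: Variance-restoring interpolation coefficient of modified SMOTE.
MODIFIED_SMOTE_COEFFICIENT = 1.5

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class AugmentationConfig:
    """Settings for one augmentation run.

    ``rate_percent`` is the number of synthetic series per original minority
    record times 100 (100% = one synthetic series per record); it must be a
    non-negative multiple of 100, with 0 meaning no augmentation.  ``seed``
    fully determines every random draw.
    """

    technique: Technique
    rate_percent: int = 0
    seed: int = 0
    bounds_policy: str = "none"  # "none" | "redraw"
    kernel_bandwidth_rule: str = "silverman"  # "silverman" | "fixed"
    fixed_bandwidth: float = 0.0
    pooled_neighbors: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "technique", Technique(self.technique))
        if self.technique not in _SAMPLER_TECHNIQUES:
            raise ValidationError(f"not a sampler technique: {self.technique}")
        if self.rate_percent < 0 or self.rate_percent % 100 != 0:
            raise ValidationError(
                f"rate_percent must be a non-negative multiple of 100, "
                f"got {self.rate_percent}"
            )
        if self.bounds_policy not in ("none", "redraw"):
            raise ValidationError(f"unknown bounds_policy {self.bounds_policy!r}")
        if self.kernel_bandwidth_rule not in ("silverman", "fixed"):
            raise ValidationError(
                f"unknown kernel_bandwidth_rule {self.kernel_bandwidth_rule!r}"
            )
        if self.fixed_bandwidth < 0:
            raise ValidationError("fixed_bandwidth must be >= 0")


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")


def smote_sample(anchor: float, neighbor: float, alpha: float) -> float:
    """Classic SMOTE draw: ``anchor + alpha * (neighbor - anchor)``."""
    _check_alpha(alpha)
    return float(anchor + alpha * (neighbor - anchor))


def modified_smote_sample(anchor: float, neighbor: float, alpha: float) -> float:
    """Variance-corrected draw: ``anchor + (3/2) * alpha * (neighbor - anchor)``."""
    _check_alpha(alpha)
    return float(anchor + MODIFIED_SMOTE_COEFFICIENT * alpha * (neighbor - anchor))


def interpolation_variance_ratio(c: float) -> float:
    """Var[synthetic] / Var[original] for the interpolation with coefficient ``c``.

    For ``s = (1 - c a) x_j + c a x_k`` with ``a ~ U(0,1)`` and i.i.d. ``x``:
    ``E[(1 - c a)^2 + (c a)^2] = 1 - c + (2/3) c^2``.  At ``c = 1`` (classic
    SMOTE) this is ``2/3``; at ``c = 3/2`` it is exactly 1.
    """
    return 1.0 - c + (2.0 / 3.0) * c * c


def solve_variance_coefficient(method: str = "closed_form") -> float:
    """Positive coefficient ``c`` restoring the synthetic variance to 1x.

    Solves ``1 - c + (2/3) c^2 = 1``, i.e. ``c (2c/3 - 1) = 0``, whose unique
    positive root is ``c = 3/2``.  ``method="numeric"`` recomputes the root by
    bracketed root-finding on the same moment expression for self-verification.
    """
    if method == "closed_form":
        return 1.5
    if method == "numeric":
        return float(brentq(lambda c: interpolation_variance_ratio(c) - 1.0, 0.5, 4.0, xtol=1e-14))
    raise ValidationError(f"unknown method {method!r}")


def silverman_bandwidth(data: Sequence[float]) -> float:
    """Silverman's rule-of-thumb bandwidth ``0.9 min(sd, IQR/1.34) n^(-1/5)``."""
    x = np.asarray(data, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * n ** (-0.2)


def smoothed_bootstrap_sample(
    data: Sequence[float], bandwidth: float, rng: np.random.Generator
) -> float:
    """One smoothed-bootstrap draw: a resampled point plus a Gaussian shift."""
    x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValidationError("smoothed bootstrap needs non-empty data")
    if bandwidth < 0:
        raise ValidationError("bandwidth must be >= 0")
    j = int(rng.integers(0, x.size))
    return float(x[j] + bandwidth * rng.standard_normal())


# ---------------------------------------------------------------------------
# vectorised draw helpers (single code path for series augmentation and
# Monte-Carlo verification of the moment contracts)
# ---------------------------------------------------------------------------


def interpolated_draws(
    pool: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    coefficient: float = 1.0,
    anchors: np.ndarray | None = None,
    anchor_offset: int | None = 0,
) -> np.ndarray:
    """Vectorised SMOTE-family draws from ``pool``.

    Anchors are selected uniformly from ``anchors`` (default: the pool
    itself); the neighbour is uniform over ``pool`` excluding the anchor
    instance when the anchor lives inside the pool (its position given by
    ``anchor_offset``); pass ``anchor_offset=None`` for a disjoint pool.
    """
    pool = np.asarray(pool, dtype=float)
    anchor_arr = pool if anchors is None else np.asarray(anchors, dtype=float)
    if anchor_arr.size == 0:
        raise ValidationError("anchor set must be non-empty")
    if pool.size < 2 and anchor_offset is not None:
        raise ValidationError("neighbour pool must hold at least 2 intervals")
    i = rng.integers(0, anchor_arr.size, n_draws)
    if anchor_offset is None:
        j = rng.integers(0, pool.size, n_draws)
    else:
        j = rng.integers(0, pool.size - 1, n_draws)
        j = j + (j >= (i + anchor_offset))
    alpha = rng.uniform(0.0, 1.0, n_draws)
    a = anchor_arr[i]
    return a + coefficient * alpha * (pool[j] - a)


def bootstrap_draws(
    data: np.ndarray, n_draws: int, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised smoothed-bootstrap draws."""
    x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValidationError("smoothed bootstrap needs non-empty data")
    j = rng.integers(0, x.size, n_draws)
    return x[j] + bandwidth * rng.standard_normal(n_draws)


# ---------------------------------------------------------------------------
# per-record and cohort-level protocol
# ---------------------------------------------------------------------------


def _draw_batch(
    source: IntervalSeries,
    neighbor_pool: np.ndarray | None,
    anchor_offset: int | None,
    config: AugmentationConfig,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    tech = config.technique
    if tech is Technique.SMOOTHED_BOOTSTRAP:
        if len(source) < 1:
            raise ValidationError(
                f"record {source.record_id!r}: smoothed bootstrap needs >= 1 interval"
            )
        if config.kernel_bandwidth_rule == "fixed":
            h = config.fixed_bandwidth
        else:
            h = silverman_bandwidth(source.intervals)
        return bootstrap_draws(source.intervals, n, h, rng)

    coeff = 1.0 if tech is Technique.SMOTE else MODIFIED_SMOTE_COEFFICIENT
    if neighbor_pool is None:
        if len(source) < 2:
            raise ValidationError(
                f"record {source.record_id!r}: SMOTE variants need >= 2 intervals"
            )
        return interpolated_draws(source.intervals, n, rng, coefficient=coeff)
    return interpolated_draws(
        neighbor_pool,
        n,
        rng,
        coefficient=coeff,
        anchors=source.intervals,
        anchor_offset=anchor_offset,
    )


def augment_series(
    source: IntervalSeries,
    config: AugmentationConfig,
    rng: np.random.Generator,
    neighbor_pool: np.ndarray | None = None,
    anchor_offset: int | None = None,
    record_id: str | None = None,
) -> IntervalSeries:
    """Generate one synthetic series of the same length as ``source``.

    Each synthetic interval comes from a uniformly selected anchor of the
    source series; SMOTE variants pair it with a neighbour drawn uniformly
    from ``neighbor_pool`` (default: the source series itself) excluding the
    anchor instance.  Determinism is guaranteed by ``rng``.
    """
    n = len(source)
    values = _draw_batch(source, neighbor_pool, anchor_offset, config, rng, n)
    if config.bounds_policy == "redraw":
        redraws = 0
        for _ in range(_MAX_REDRAWS):
            bad = (values <= 0) | (values > 300.0)
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            redraws += n_bad
            values[bad] = _draw_batch(
                source, neighbor_pool, anchor_offset, config, rng, n_bad
            )
        else:
            raise ValidationError(
                f"record {source.record_id!r}: could not redraw into (0, 300] "
                f"after {_MAX_REDRAWS} rounds"
            )
        if redraws:
            logger.debug(
                "record %s: %d out-of-range draws redrawn", source.record_id, redraws
            )
    return IntervalSeries(
        record_id=record_id or f"{source.record_id}_{config.technique.value}_syn",
        mechanism=source.mechanism,
        intervals=values,
        provenance=Provenance.SYNTHETIC,
        technique=config.technique,
        source_record_id=source.record_id,
    )


def augment_cohort(
    cohort: Cohort,
    config: AugmentationConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Add ``rate_percent / 100`` synthetic series per original minority record.

    Original series are never modified, reordered or dropped; the majority
    class is untouched.  Synthetic record ids are deterministic functions of
    the source record id and replicate index, and the whole output is a
    deterministic function of ``(cohort, config.seed)``.
    """
    if config.rate_percent == 0:
        return cohort
    if rng is None:
        rng = np.random.default_rng(config.seed)
    minority = cohort.minority_mechanism
    sources = [
        s
        for s in cohort.series
        if s.mechanism is minority and s.provenance is Provenance.ORIGINAL
    ]
    if not sources:
        raise ValidationError("cohort has no original minority-class series")

    pool = None
    offsets: dict[str, int] = {}
    if config.pooled_neighbors:
        chunks, pos = [], 0
        for s in sources:
            offsets[s.record_id] = pos
            chunks.append(s.intervals)
            pos += len(s)
        pool = np.concatenate(chunks)

    replicates = config.rate_percent // 100
    synthetic: list[IntervalSeries] = []
    for s in sources:
        for k in range(1, replicates + 1):
            synthetic.append(
                augment_series(
                    s,
                    config,
                    rng,
                    neighbor_pool=pool,
                    anchor_offset=offsets.get(s.record_id) if pool is not None else None,
                    record_id=f"{s.record_id}_{config.technique.value}_{k:03d}",
                )
            )
    name = f"{cohort.name}+{config.technique.value}@{config.rate_percent}%"
    return cohort.with_series(synthetic, name=name)
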