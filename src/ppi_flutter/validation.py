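"""Statistical battery comparing augmented minority data to the original.

Four criteria judge how faithfully an oversampling technique reproduces the
original minority-class interval distribution:

1. binned empirical CDF (5 ms bins) -- maximum absolute difference,
2. boxplot quartiles -- absolute differences at 25/50/75%,
3. two-sample Kolmogorov-Smirnov test -- p-value as a similarity score
   (mean +/- sd over replicate augmented datasets),
4. descriptive moments -- signed percent differences of mean, variance and
   skewness relative to the original.

:func:`validate_augmentation` runs the battery for several techniques over
``n_replicates`` independently generated augmented datasets (default 100) and
ranks the techniques per criterion (rank 1 = best, ties share the better
rank).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ppi_flutter.augmentation import AugmentationConfig, augment_cohort
from ppi_flutter.interval_data import Cohort, Provenance, Technique, ValidationError
from ppi_flutter.util import derive_seed

DEFAULT_BIN_WIDTH_MS = 5.0

#: criterion name -> True if larger values indicate better agreement
CRITERION_HIGHER_IS_BETTER: dict[str, bool] = {
    "cdf": False,
    "quartiles": False,
    "ks": True,
    "mean": False,
    "variance": False,
    "skewness": False,
}


@dataclass(frozen=True)
class BinnedCDF:
    """Empirical CDF evaluated at bin edges (multiples of the bin width)."""

    edges: np.ndarray
    fractions: np.ndarray


@dataclass(frozen=True)
class KSSimilarity:
    mean_p: float
    sd_p: float
    n_used: int
    n_skipped: int = 0


@dataclass(frozen=True)
class MomentDiffs:
    """Signed percent differences ``100 (augmented - original) / original``.

    Moments whose original value is zero cannot be expressed as a percentage;
    for those the *absolute* difference is reported instead and the moment
    name is listed in ``absolute_fallback``.
    """

    mean_pct: float
    variance_pct: float
    skewness_pct: float
    absolute_fallback: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean_pct,
            "variance": self.variance_pct,
            "skewness": self.skewness_pct,
        }


def empirical_cdf(data: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH_MS) -> BinnedCDF:
    """Binned empirical CDF: fraction of data <= each bin edge.

    Edges are the multiples of ``bin_width`` from the first multiple >= min(data)
    to the first multiple >= max(data); the final fraction is 1.
    """
    x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValidationError("empirical_cdf needs non-empty data")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    k_lo = math.ceil(np.min(x) / bin_width)
    k_hi = math.ceil(np.max(x) / bin_width)
    edges = bin_width * np.arange(k_lo, k_hi + 1)
    fractions = np.searchsorted(np.sort(x), edges, side="right") / x.size
    return BinnedCDF(edges=edges, fractions=fractions)


def cdf_max_abs_diff(
    original: Sequence[float],
    augmented: Sequence[float],
    bin_width: float = DEFAULT_BIN_WIDTH_MS,
) -> float:
    """Max absolute difference of the two binned CDFs on a common edge grid."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(augmented, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("cdf comparison needs non-empty data")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = bin_width * np.arange(math.ceil(lo / bin_width), math.ceil(hi / bin_width) + 1)
    fa = np.searchsorted(np.sort(a), edges, side="right") / a.size
    fb = np.searchsorted(np.sort(b), edges, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def quartile_differences(
    original: Sequence[float], augmented: Sequence[float]
) -> np.ndarray:
    """Absolute differences of the 25/50/75% sample quartiles (ms).

    Quartiles use linear interpolation between order statistics.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(augmented, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("quartile comparison needs non-empty data")
    q = [0.25, 0.5, 0.75]
    return np.abs(np.quantile(a, q) - np.quantile(b, q))


def ks_similarity(
    original: Sequence[float], augmented_replicates: Sequence[Sequence[float]]
) -> KSSimilarity:
    """Two-sample asymptotic KS p-value per replicate, summarised as mean +/- sd.

    Replicates with fewer than 2 points are skipped with a warning (counted).
    """
    a = np.asarray(original, dtype=float)
    if len(augmented_replicates) == 0:
        raise ValidationError("ks_similarity needs >= 1 replicate")
    pvals = []
    skipped = 0
    for rep in augmented_replicates:
        r = np.asarray(rep, dtype=float)
        if r.size < 2:
            warnings.warn("skipping KS replicate with < 2 points", stacklevel=2)
            skipped += 1
            continue
        pvals.append(float(stats.ks_2samp(a, r, method="asymp").pvalue))
    if not pvals:
        raise ValidationError("all KS replicates were too short")
    mean_p = float(np.mean(pvals))
    sd_p = float(np.std(pvals, ddof=1)) if len(pvals) > 1 else 0.0
    return KSSimilarity(mean_p=mean_p, sd_p=sd_p, n_used=len(pvals), n_skipped=skipped)


def _sample_moments(x: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    skew = 0.0 if np.ptp(x) == 0 else float(stats.skew(x, bias=(x.size < 3)))
    return mean, var, skew


def moment_percent_differences(
    original: Sequence[float], augmented: Sequence[float]
) -> MomentDiffs:
    """Signed percent differences of mean, variance and skewness."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(augmented, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("moment comparison needs >= 2 points per dataset")
    names = ("mean", "variance", "skewness")
    orig = _sample_moments(a)
    aug = _sample_moments(b)
    out = []
    fallback = []
    for name, o, g in zip(names, orig, aug):
        if o == 0.0:
            out.append(g - o)
            fallback.append(name)
        else:
            out.append(100.0 * (g - o) / o)
    return MomentDiffs(
        mean_pct=out[0],
        variance_pct=out[1],
        skewness_pct=out[2],
        absolute_fallback=tuple(fallback),
    )


def rank_techniques(
    table: Mapping[str, Mapping[str, float]],
    higher_is_better: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Rank techniques per criterion; 1 = best, ties share the better rank.

    ``table`` maps criterion -> technique -> value (values already oriented,
    e.g. absolute moment differences).  Exactly three techniques with a value
    for every criterion are required.
    """
    directions = dict(CRITERION_HIGHER_IS_BETTER)
    if higher_is_better:
        directions.update(higher_is_better)
    techniques: set[str] = set()
    for crit, row in table.items():
        techniques.update(row)
    if len(techniques) != 3:
        raise ValidationError(f"expected exactly 3 techniques, got {sorted(techniques)}")
    ranks = {}
    for crit, row in table.items():
        missing = techniques - set(row)
        if missing:
            raise ValidationError(f"criterion {crit!r} missing techniques {sorted(missing)}")
        hib = directions.get(crit, False)
        vals = {t: row[t] for t in techniques}

        def beats(u: str, t: str) -> bool:
            return vals[u] > vals[t] if hib else vals[u] < vals[t]

        ranks[crit] = {
            t: 1 + sum(1 for u in techniques if beats(u, t)) for t in techniques
        }
    df = pd.DataFrame(ranks).T
    return df[sorted(df.columns)]


@dataclass(frozen=True)
class ValidationReport:
    """Replicate-averaged battery results for a set of techniques at one rate."""

    rate_percent: int
    n_replicates: int
    cdf_bin_width: float
    cdf_max_abs_diff: dict[str, float]
    quartile_diffs: dict[str, np.ndarray]
    ks: dict[str, KSSimilarity]
    moment_diffs: dict[str, MomentDiffs]
    ranks: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Flat table (one row per technique) of the averaged criteria."""
        rows = []
        for tech in sorted(self.cdf_max_abs_diff):
            q = self.quartile_diffs[tech]
            m = self.moment_diffs[tech]
            rows.append(
                {
                    "technique": tech,
                    "rate_percent": self.rate_percent,
                    "cdf_max_abs_diff": self.cdf_max_abs_diff[tech],
                    "quartile_diff_25": q[0],
                    "quartile_diff_50": q[1],
                    "quartile_diff_75": q[2],
                    "ks_p_mean": self.ks[tech].mean_p,
                    "ks_p_sd": self.ks[tech].sd_p,
                    "mean_pct_diff": m.mean_pct,
                    "variance_pct_diff": m.variance_pct,
                    "skewness_pct_diff": m.skewness_pct,
                }
            )
        return pd.DataFrame(rows)


def _minority_pool(cohort: Cohort) -> np.ndarray:
    minority = cohort.minority_mechanism
    chunks = [
        s.intervals
        for s in cohort
        if s.mechanism is minority and s.provenance is Provenance.ORIGINAL
    ]
    if not chunks:
        raise ValidationError("cohort has no original minority series")
    return np.concatenate(chunks)


def validate_augmentation(
    cohort: Cohort,
    techniques: Sequence[Technique | str] = (
        Technique.SMOTE,
        Technique.MODIFIED_SMOTE,
        Technique.SMOOTHED_BOOTSTRAP,
    ),
    rate_percent: int = 400,
    n_replicates: int = 100,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH_MS,
) -> ValidationReport:
    """Run the four-test battery on ``cohort`` for each technique.

    For every technique and replicate, a fresh augmented cohort is generated
    (seeded deterministically from ``seed``); the "augmented dataset" pools
    the original minority intervals with all synthetic intervals.  CDF,
    quartile and moment criteria are averaged over replicates; the KS
    criterion is summarised as mean +/- sd of the per-replicate p-value.
    """
    techniques = [Technique(t) for t in techniques]
    original = _minority_pool(cohort)

    cdf_d: dict[str, float] = {}
    quart: dict[str, np.ndarray] = {}
    ks: dict[str, KSSimilarity] = {}
    moments: dict[str, MomentDiffs] = {}
    for tech in techniques:
        cdf_vals, quart_vals, pools, mom_vals = [], [], [], []
        for rep in range(n_replicates):
            cfg = AugmentationConfig(
                technique=tech,
                rate_percent=rate_percent,
                seed=derive_seed(seed, "validate", tech.value, rep),
            )
            augmented_cohort = augment_cohort(cohort, cfg)
            synth = np.concatenate(
                [s.intervals for s in augmented_cohort.synthetics()]
            )
            pool = np.concatenate([original, synth])
            pools.append(pool)
            cdf_vals.append(cdf_max_abs_diff(original, pool, bin_width))
            quart_vals.append(quartile_differences(original, pool))
            mom_vals.append(moment_percent_differences(original, pool))
        key = tech.value
        cdf_d[key] = float(np.mean(cdf_vals))
        quart[key] = np.mean(quart_vals, axis=0)
        ks[key] = ks_similarity(original, pools)
        moments[key] = MomentDiffs(
            mean_pct=float(np.mean([m.mean_pct for m in mom_vals])),
            variance_pct=float(np.mean([m.variance_pct for m in mom_vals])),
            skewness_pct=float(np.mean([m.skewness_pct for m in mom_vals])),
        )

    table = {
        "cdf": cdf_d,
        "quartiles": {t: float(np.sum(quart[t])) for t in quart},
        "ks": {t: ks[t].mean_p for t in ks},
        "mean": {t: abs(moments[t].mean_pct) for t in moments},
        "variance": {t: abs(moments[t].variance_pct) for t in moments},
        "skewness": {t: abs(moments[t].skewness_pct) for t in moments},
    }
    ranks = rank_techniques(table) if len(techniques) == 3 else pd.DataFrame()
    return ValidationReport(
        rate_percent=rate_percent,
        n_replicates=n_replicates,
        cdf_bin_width=bin_width,
        cdf_max_abs_diff=cdf_d,
        quartile_diffs=quart,
        ks=ks,
        moment_diffs=moments,
        ranks=ranks,
    )
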