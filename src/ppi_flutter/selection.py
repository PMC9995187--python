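"""Filter and wrapper feature-relevance assessment.

The *filter* method tests each feature for a class difference in medians with
the two-sided Wilcoxon rank-sum test.  The *wrapper* method exhaustively
evaluates every non-empty feature subset with a classifier: for each subset
length L, every feature in the maximum-accuracy length-L subset is credited 1
point, and a feature's score is its credited count divided by the number of
features, so scores live on the grid {0, 1/p, ..., 1}.  A score near 1 marks
a feature that keeps company with the best subset at every size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import clone

from ppi_flutter.classify import make_classifier, stratified_folds
from ppi_flutter.features import FEATURE_COLUMNS
from ppi_flutter.interval_data import ValidationError

#: features with a filter p-value below this are flagged univariately relevant
FILTER_ALPHA = 0.05
#: wrapper-score threshold for relevance
WRAPPER_THRESHOLD = 0.8


def _split_matrix(
    features: pd.DataFrame | np.ndarray, labels: Sequence | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURE_COLUMNS if c in features.columns]
        if not cols:
            cols = [c for c in features.columns if pd.api.types.is_numeric_dtype(features[c])]
        X = features[cols].to_numpy(dtype=float)
        if labels is None:
            if "mechanism" not in features.columns:
                raise ValidationError("labels required when no 'mechanism' column present")
            labels = features["mechanism"].to_numpy()
        names = cols
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValidationError("labels required for array input")
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValidationError("exactly two classes are required")
    return X, y, names


def rank_sum_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the rank-sum distribution when both groups have at
    most 10 samples and the pooled data is tie-free; tie-corrected normal
    approximation otherwise.  Identical constant groups return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups need >= 1 sample")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and tie_free) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def filter_pvalues(
    features: pd.DataFrame | np.ndarray, labels: Sequence | None = None
) -> pd.Series:
    """Per-feature two-sided rank-sum p-values between the two classes."""
    X, y, names = _split_matrix(features, labels)
    classes = np.unique(y)
    mask = y == classes[0]
    pvals = [rank_sum_pvalue(X[mask, j], X[~mask, j]) for j in range(X.shape[1])]
    return pd.Series(pvals, index=names, name="filter_p")


def enumerate_subsets(p: int) -> dict[int, list[tuple[int, ...]]]:
    """All 2^p - 1 non-empty feature-index subsets, grouped by length.

    Group L holds the C(p, L) subsets in lexicographic order.  Guarded to
    p <= 20 against combinatorial blow-up.
    """
    if not 1 <= p <= 20:
        raise ValidationError(f"feature count must be in [1, 20], got {p}")
    return {
        length: list(combinations(range(p), length)) for length in range(1, p + 1)
    }


@dataclass(frozen=True)
class WrapperResult:
    """Per-feature wrapper scores plus the full evaluation log."""

    scores: pd.Series
    best_subsets: dict[int, tuple[str, ...]]
    log: pd.DataFrame

    @property
    def credited_counts(self) -> pd.Series:
        return (self.scores * len(self.scores)).round().astype(int)


def subset_accuracies(
    X: np.ndarray,
    y: np.ndarray,
    subsets: Sequence[tuple[int, ...]],
    classifier: str,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
) -> list[float]:
    """Cross-validated accuracy of a classifier on each column subset.

    A subset on which the classifier raises is scored 0 with a warning rather
    than silently dropped.
    """
    template = make_classifier(classifier)
    out = []
    for cols in subsets:
        Xs = X[:, cols]
        try:
            accs = []
            for train, test in folds:
                model = clone(template)
                model.fit(Xs[train], y[train])
                accs.append(float(np.mean(model.predict(Xs[test]) == y[test])))
            out.append(float(np.mean(accs)))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"classifier failed on subset {cols}: {exc}", stacklevel=2)
            out.append(0.0)
    return out


def wrapper_scores(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence | None = None,
    classifier: str = "log",
    n_folds: int = 5,
    seed: int = 0,
) -> WrapperResult:
    """Exhaustive wrapper scoring of every feature with one classifier.

    The same stratified ``n_folds``-fold split (seeded) is reused for every
    subset so accuracies are comparable; ties for the best subset at a length
    go to the lexicographically first subset.
    """
    X, y, names = _split_matrix(features, labels)
    p = X.shape[1]
    folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    groups = enumerate_subsets(p)
    credits = np.zeros(p)
    best: dict[int, tuple[str, ...]] = {}
    log_rows = []
    for length, subsets in groups.items():
        accs = subset_accuracies(X, y, subsets, classifier, folds)
        best_idx = int(np.argmax(accs))  # argmax keeps the first (lexicographic) tie
        for cols, acc in zip(subsets, accs):
            log_rows.append(
                {
                    "length": length,
                    "subset": ",".join(names[c] for c in cols),
                    "accuracy": acc,
                    "best": cols == subsets[best_idx],
                }
            )
        for c in subsets[best_idx]:
            credits[c] += 1
        best[length] = tuple(names[c] for c in subsets[best_idx])
    scores = pd.Series(credits / p, index=names, name=f"wrapper_{classifier}")
    return WrapperResult(scores=scores, best_subsets=best, log=pd.DataFrame(log_rows))


def score_table(
    features: pd.DataFrame,
    labels: Sequence | None = None,
    classifiers: Sequence[str] = ("lda", "log", "svm"),
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side filter p-values and per-classifier wrapper scores.

    The combined relevance rule flags a feature when its wrapper score reaches
    ``WRAPPER_THRESHOLD`` for a majority of classifiers; rows are ordered by
    mean wrapper score (descending), then filter p-value (ascending).
    """
    filt = filter_pvalues(features, labels)
    table = pd.DataFrame({"filter_p": filt})
    wrap_cols = []
    for clf in classifiers:
        res = wrapper_scores(features, labels, classifier=clf, n_folds=n_folds, seed=seed)
        col = f"wrapper_{clf}"
        table[col] = res.scores
        wrap_cols.append(col)
    table["filter_relevant"] = table["filter_p"] < FILTER_ALPHA
    votes = (table[wrap_cols] >= WRAPPER_THRESHOLD).sum(axis=1)
    table["wrapper_relevant"] = votes > len(wrap_cols) / 2
    table["relevant"] = table["wrapper_relevant"]
    order = table[wrap_cols].mean(axis=1)
    table = table.assign(_order=-order).sort_values(["_order", "filter_p"]).drop(columns="_order")
    table.index.name = "feature"
    return table
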