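"""Linear-classifier evaluation and best-augmentation-rate selection.

Three linear classifiers are supported -- linear discriminant analysis
(``"lda"``), logistic regression (``"log"``) and a linear-kernel support
vector machine (``"svm"``) -- each behind a per-fold standardisation step.
Metrics follow the clinical orientation used throughout the package: MAFL is
the positive class, so *sensitivity* is the MAFL true-positive rate and
*specificity* the FAFL true-negative rate.  Under the 41:5 imbalance a
trivial majority-class predictor scores ~89% accuracy with 0% specificity,
which is why specificity is the quantity the augmentation study watches.

Cross-validation is stratified; when the cohort contains synthetic series,
each one is forced into the fold of its source record (a leakage guard), so a
classifier is never tested on a record whose synthetic offspring it trained
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ppi_flutter.features import FEATURE_COLUMNS
from ppi_flutter.interval_data import Mechanism, Provenance, ValidationError

CLASSIFIERS = ("lda", "log", "svm")

#: Fixed classifier settings, logged with every report for reproducibility.
CLASSIFIER_SETTINGS: dict[str, dict] = {
    "lda": {"solver": "svd"},  # pooled covariance
    "log": {"C": 1e4, "max_iter": 5000},  # minimal regularisation
    "svm": {"kernel": "linear", "C": 1.0},
}

POSITIVE_CLASS = Mechanism.MAFL.value


def make_classifier(spec: str) -> Pipeline:
    """Standardiser + linear classifier pipeline for ``spec`` in {lda, log, svm}."""
    if spec == "lda":
        clf = LinearDiscriminantAnalysis(**CLASSIFIER_SETTINGS["lda"])
    elif spec == "log":
        clf = LogisticRegression(**CLASSIFIER_SETTINGS["log"])
    elif spec == "svm":
        clf = SVC(**CLASSIFIER_SETTINGS["svm"])
    else:
        raise ValidationError(f"unknown classifier {spec!r}; choose from {CLASSIFIERS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass(frozen=True)
class Confusion:
    """Per-fold confusion counts with MAFL as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class PerformanceReport:
    """Fold-averaged accuracy/sensitivity/specificity (percent) per classifier."""

    classifier: str
    technique: str
    rate_percent: int
    fold_confusions: tuple[Confusion, ...]
    settings: dict = field(default_factory=dict)

    def _stats(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(c, attr) for c in self.fold_confusions])
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(np.mean(vals)), sd

    @property
    def accuracy(self) -> tuple[float, float]:
        return self._stats("accuracy")

    @property
    def sensitivity(self) -> tuple[float, float]:
        return self._stats("sensitivity")

    @property
    def specificity(self) -> tuple[float, float]:
        return self._stats("specificity")

    def as_row(self) -> dict:
        return {
            "classifier": self.classifier,
            "technique": self.technique,
            "rate_percent": self.rate_percent,
            "accuracy_mean": self.accuracy[0],
            "accuracy_sd": self.accuracy[1],
            "sensitivity_mean": self.sensitivity[0],
            "sensitivity_sd": self.sensitivity[1],
            "specificity_mean": self.specificity[0],
            "specificity_sd": self.specificity[1],
        }


def stratified_folds(
    y: Sequence, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified K-fold (train, test) index pairs."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def assign_folds(
    meta: pd.DataFrame, n_folds: int = 5, seed: int = 0, grouped: bool = True
) -> np.ndarray:
    """Fold id per row; synthetic series share their source record's fold.

    ``meta`` needs columns record_id, mechanism, provenance, source_record_id.
    With ``grouped=False`` synthetic rows are stratified independently (for
    sensitivity analysis only -- this leaks information between folds).
    """
    n = len(meta)
    fold = np.full(n, -1, dtype=int)
    provenance = meta["provenance"].to_numpy()
    y = meta["mechanism"].to_numpy()
    if not grouped:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (_, test) in enumerate(skf.split(np.zeros(n), y)):
            fold[test] = k
        return fold

    orig_idx = np.flatnonzero(provenance == Provenance.ORIGINAL.value)
    if orig_idx.size < n_folds:
        raise ValidationError("fewer original records than folds; use fewer folds")
    try:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (_, test) in enumerate(skf.split(np.zeros(orig_idx.size), y[orig_idx])):
            fold[orig_idx[test]] = k
    except ValueError as exc:
        raise ValidationError(f"stratified split failed: {exc}; use fewer folds") from exc

    record_fold = dict(zip(meta["record_id"].to_numpy()[orig_idx], fold[orig_idx]))
    synth_idx = np.flatnonzero(provenance == Provenance.SYNTHETIC.value)
    for i in synth_idx:
        src = meta["source_record_id"].iat[i]
        if src not in record_fold:
            raise ValidationError(
                f"synthetic record {meta['record_id'].iat[i]!r} has unknown source {src!r}"
            )
        fold[i] = record_fold[src]
    return fold


def _confusions(
    X: np.ndarray,
    y: np.ndarray,
    fold: np.ndarray,
    classifier: str,
) -> tuple[Confusion, ...]:
    template = make_classifier(classifier)
    out = []
    for k in sorted(set(fold)):
        test = fold == k
        train = ~test
        y_tr = y[train]
        if len(set(y_tr)) < 2:
            raise ValidationError(
                f"fold {k}: training data holds a single class; use fewer folds"
            )
        if not np.any((y[test] == POSITIVE_CLASS)) or np.all(y[test] == POSITIVE_CLASS):
            raise ValidationError(
                f"fold {k}: test data misses a class; use fewer folds"
            )
        model = clone(template)
        model.fit(X[train], y_tr)
        pred = model.predict(X[test])
        truth = y[test]
        pos = truth == POSITIVE_CLASS
        out.append(
            Confusion(
                tp=int(np.sum(pos & (pred == POSITIVE_CLASS))),
                fn=int(np.sum(pos & (pred != POSITIVE_CLASS))),
                tn=int(np.sum(~pos & (pred != POSITIVE_CLASS))),
                fp=int(np.sum(~pos & (pred == POSITIVE_CLASS))),
            )
        )
    return tuple(out)


def evaluate_classifier(
    features: pd.DataFrame,
    classifier: str = "log",
    n_folds: int = 5,
    seed: int = 0,
    grouped: bool = True,
    technique: str = "none",
    rate_percent: int = 0,
    columns: Sequence[str] | None = None,
) -> PerformanceReport:
    """Stratified ``n_folds``-fold evaluation of one classifier.

    ``features`` is a :func:`ppi_flutter.features.build_feature_matrix` frame;
    standardisation is fitted per training fold inside the pipeline.
    """
    cols = list(columns) if columns is not None else FEATURE_COLUMNS
    X = features[cols].to_numpy(dtype=float)
    y = features["mechanism"].to_numpy()
    fold = assign_folds(features, n_folds=n_folds, seed=seed, grouped=grouped)
    confusions = _confusions(X, y, fold, classifier)
    return PerformanceReport(
        classifier=classifier,
        technique=technique,
        rate_percent=rate_percent,
        fold_confusions=confusions,
        settings=dict(CLASSIFIER_SETTINGS[classifier]),
    )


def specificity_curve(
    features: pd.DataFrame,
    classifier: str = "log",
    n_folds: int = 5,
    seed: int = 0,
    grouped: bool = True,
    lengths: Sequence[int] | None = None,
    columns: Sequence[str] | None = None,
) -> np.ndarray:
    """Maximum cross-validated specificity per feature-subset length (percent).

    For each length L, every length-L subset of the feature columns is
    evaluated on the same fold assignment and the best specificity retained.
    """
    from ppi_flutter.selection import enumerate_subsets  # local: avoids cycle

    cols = list(columns) if columns is not None else FEATURE_COLUMNS
    cols = [c for c in cols if c in features.columns]
    X = features[cols].to_numpy(dtype=float)
    y = features["mechanism"].to_numpy()
    fold = assign_folds(features, n_folds=n_folds, seed=seed, grouped=grouped)
    groups = enumerate_subsets(len(cols))
    wanted = list(lengths) if lengths is not None else sorted(groups)
    curve = []
    for length in wanted:
        best = 0.0
        for subset in groups[length]:
            confs = _confusions(X[:, subset], y, fold, classifier)
            spec = float(np.mean([c.specificity for c in confs]))
            best = max(best, spec)
        curve.append(best)
    return np.asarray(curve)


@dataclass(frozen=True)
class RateSelectionResult:
    """Distance-to-average-curve selection of the best augmentation rate."""

    rates: tuple[int, ...]
    curves: dict[int, np.ndarray]
    average_curve: np.ndarray
    distances: dict[int, float]
    best_rate_percent: int


def select_best_rate(curves: Mapping[int, Sequence[float]]) -> RateSelectionResult:
    """Pick the rate whose specificity curve is closest (L2) to the average.

    The average curve is the pointwise mean over rates; ties are resolved to
    the smallest rate, preferring the minimum synthetic ratio.
    """
    rates = sorted(int(r) for r in curves)
    if len(rates) < 2:
        raise ValidationError("need >= 2 rates to select among")
    arrs = {r: np.asarray(curves[r], dtype=float) for r in rates}
    lengths = {a.size for a in arrs.values()}
    if len(lengths) != 1:
        raise ValidationError(f"curve length mismatch: {sorted(lengths)}")
    avg = np.mean([arrs[r] for r in rates], axis=0)
    dists = {r: float(np.linalg.norm(arrs[r] - avg)) for r in rates}
    dmin = min(dists.values())
    best = min(r for r in rates if np.isclose(dists[r], dmin, rtol=0, atol=1e-12))
    return RateSelectionResult(
        rates=tuple(rates),
        curves=arrs,
        average_curve=avg,
        distances=dists,
        best_rate_percent=best,
    )
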