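"""End-to-end study orchestration: one reproducible run, one report bundle.

``run_pipeline`` executes filter -> augment (per technique x rate) ->
validation battery -> feature extraction -> feature selection -> classifier
evaluation -> best-rate selection, and writes every table plus a manifest
into an output directory.  All randomness flows from a single master seed,
expanded into deterministic per-stage substreams, so re-running the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import ppi_flutter
from ppi_flutter.augmentation import AugmentationConfig, augment_cohort
from ppi_flutter.classify import (
    CLASSIFIER_SETTINGS,
    evaluate_classifier,
    select_best_rate,
    specificity_curve,
)
from ppi_flutter.features import build_feature_matrix
from ppi_flutter.interval_data import (
    Cohort,
    Technique,
    ValidationError,
    filter_intervals,
    read_cohort,
    write_cohort,
)
from ppi_flutter.selection import score_table
from ppi_flutter.simulate import CohortSpec, generate_cohort
from ppi_flutter.util import derive_seed
from ppi_flutter.validation import validate_augmentation

DEFAULT_TECHNIQUES = ("smote", "modified_smote", "smoothed_bootstrap")
DEFAULT_RATES = (100, 200, 300, 400, 500, 600, 700, 800)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``cohort_path`` (CSV/JSON cohort file) or ``spec`` (synthetic
    cohort generator settings) supplies the input; with neither, the default
    synthetic cohort is generated.  ``curve_lengths`` bounds the subset
    lengths scanned for the specificity curves (the exhaustive scan over all
    10 features is expensive); ``selection_rate`` is the rate at which the
    filter/wrapper score tables are produced.
    """

    cohort_path: str | None = None
    spec: CohortSpec | None = None
    techniques: tuple[str, ...] = DEFAULT_TECHNIQUES
    rates: tuple[int, ...] = DEFAULT_RATES
    classifiers: tuple[str, ...] = ("lda", "log", "svm")
    folds: int = 5
    validation_replicates: int = 100
    run_selection: bool = True
    selection_rate: int = 400
    curve_lengths: tuple[int, ...] | None = None
    seed: int = 0
    output_dir: str = "ppi_flutter_run"
    overwrite: bool = False

    def to_jsonable(self) -> dict:
        d = asdict(self)
        if self.spec is not None:
            d["spec"] = asdict(self.spec)
        d.pop("overwrite")  # I/O flag, not part of the scientific configuration
        return d


def _load_cohort(config: RunConfig) -> Cohort:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    spec = config.spec or CohortSpec(seed=derive_seed(config.seed, "simulate"))
    return generate_cohort(spec)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study flow; returns the bundle directory.

    Outputs: ``cohort.csv`` (filtered input), ``validation.csv``,
    ``performance.csv``, ``scores_<technique>.csv``, ``rate_selection.json``
    and ``manifest.json``.  Any stage failure aborts with the stage name.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise ValidationError(
            f"output directory {out} is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_cohort(config)
    cohort = Cohort(
        tuple(filter_intervals(s) for s in cohort.series), name=cohort.name
    )
    write_cohort(cohort, out / "cohort.csv")

    rates = sorted(set(config.rates))
    positive_rates = [r for r in rates if r > 0]
    performance_rows = []
    validation_frames = []
    curves: dict[str, dict[str, dict[int, list[float]]]] = {}
    base_features = build_feature_matrix(cohort)

    # baseline (no augmentation)
    for clf in config.classifiers:
        rep = evaluate_classifier(
            base_features,
            classifier=clf,
            n_folds=config.folds,
            seed=derive_seed(config.seed, "eval", "none", 0),
        )
        performance_rows.append(rep.as_row())

    for tech in config.techniques:
        tech = Technique(tech)
        if positive_rates and config.validation_replicates > 0:
            for rate in positive_rates:
                report = validate_augmentation(
                    cohort,
                    techniques=[tech],
                    rate_percent=rate,
                    n_replicates=config.validation_replicates,
                    seed=derive_seed(config.seed, "validate", tech.value, rate),
                )
                validation_frames.append(report.to_frame())
        for rate in positive_rates:
            cfg = AugmentationConfig(
                technique=tech,
                rate_percent=rate,
                seed=derive_seed(config.seed, "augment", tech.value, rate),
            )
            augmented = augment_cohort(cohort, cfg)
            feats = build_feature_matrix(augmented)
            for clf in config.classifiers:
                rep = evaluate_classifier(
                    feats,
                    classifier=clf,
                    n_folds=config.folds,
                    seed=derive_seed(config.seed, "eval", tech.value, rate),
                    technique=tech.value,
                    rate_percent=rate,
                )
                performance_rows.append(rep.as_row())
                if config.curve_lengths:
                    curve = specificity_curve(
                        feats,
                        classifier=clf,
                        n_folds=config.folds,
                        seed=derive_seed(config.seed, "curve", tech.value, rate),
                        lengths=config.curve_lengths,
                    )
                    curves.setdefault(tech.value, {}).setdefault(clf, {})[rate] = [
                        float(v) for v in curve
                    ]

    pd.DataFrame(performance_rows).to_csv(out / "performance.csv", index=False)
    if validation_frames:
        pd.concat(validation_frames, ignore_index=True).to_csv(
            out / "validation.csv", index=False
        )

    rate_selection = {}
    for tech, per_clf in curves.items():
        for clf, per_rate in per_clf.items():
            if len(per_rate) >= 2:
                res = select_best_rate(per_rate)
                rate_selection[f"{tech}/{clf}"] = {
                    "best_rate_percent": res.best_rate_percent,
                    "distances": {str(r): res.distances[r] for r in res.rates},
                    "curves": {str(r): list(map(float, res.curves[r])) for r in res.rates},
                    "average_curve": list(map(float, res.average_curve)),
                }
    if rate_selection:
        (out / "rate_selection.json").write_text(
            json.dumps(rate_selection, indent=1, sort_keys=True)
        )

    if config.run_selection:
        for tech in config.techniques:
            tech = Technique(tech)
            rate = config.selection_rate
            if rate > 0:
                cfg = AugmentationConfig(
                    technique=tech,
                    rate_percent=rate,
                    seed=derive_seed(config.seed, "augment", tech.value, rate),
                )
                feats = build_feature_matrix(augment_cohort(cohort, cfg))
            else:
                feats = base_features
            table = score_table(
                feats,
                classifiers=config.classifiers,
                n_folds=config.folds,
                seed=derive_seed(config.seed, "select", tech.value, rate),
            )
            table.to_csv(out / f"scores_{tech.value}.csv")

    manifest = {
        "package_version": ppi_flutter.__version__,
        "config": config.to_jsonable(),
        "classifier_settings": CLASSIFIER_SETTINGS,
        "n_series_input": len(cohort),
        "class_counts": {m.value: c for m, c in cohort.class_counts().items()},
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
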