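"""Classifier zoo, confusion-matrix evaluation and the CV experiment driver.

Four classifier families are benchmarked with the hyperparameters of the
study: random forest (100 trees, Gini, min_samples_split 2, min_samples_leaf
1), gradient-boosted trees (gbtree booster, learning rate 0.3, min split
loss 0, max depth 6, uniform sampling), Gaussian naive Bayes (no priors,
var_smoothing 1e-9) and a small feed-forward neural network (32/16/1 units,
ReLU hidden activations and a sigmoid output unit, 200 epochs).  The
positive class is "cancer" (target 1), so TP counts cancer analogs
classified as cancer.

Tree and Bayes families are exactly seed-deterministic; the neural family
is seeded but only tolerance-tested.  Feature standardization is applied
inside the neural family only — the tree and Bayes families consume the raw
feature rows.
"""

from __future__ import annotations

import json
import logging
import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .data import FoldPlan, LabeledDataset
from .exceptions import FPScreenError

__all__ = [
    "CLASSICAL_FAMILIES",
    "ALL_FAMILIES",
    "ClassifierSpec",
    "ConfusionMatrix",
    "FoldResult",
    "ClassifierReport",
    "EvaluationReport",
    "train",
    "evaluate",
    "metrics",
    "run_experiment",
]

logger = logging.getLogger(__name__)

CLASSICAL_FAMILIES = ("random-forest", "gradient-boosted-trees", "gaussian-naive-bayes")
ALL_FAMILIES = CLASSICAL_FAMILIES + ("neural-net",)

# Printed hyperparameter defaults per family.
_DEFAULTS: dict[str, dict[str, Any]] = {
    "random-forest": {
        "n_estimators": 100,
        "criterion": "gini",
        "min_samples_split": 2,
        "min_samples_leaf": 1,
    },
    "gradient-boosted-trees": {
        "booster": "gbtree",
        "learning_rate": 0.3,
        "min_split_loss": 0.0,
        "max_depth": 6,
        "sampling_method": "uniform",
    },
    "gaussian-naive-bayes": {
        "priors": None,
        "var_smoothing": 1e-9,
    },
    "neural-net": {
        "hidden_units": (32, 16),
        "activation": "relu",
        "epochs": 200,
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus hyperparameter overrides and a seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _DEFAULTS:
            raise FPScreenError(
                f"unknown classifier family {self.family!r}; choose from {ALL_FAMILIES}"
            )
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.family])
        if unknown:
            raise FPScreenError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )

    def resolved(self) -> dict[str, Any]:
        params = dict(_DEFAULTS[self.family])
        params.update(self.hyperparameters)
        return params

    def build(self):
        p = self.resolved()
        if self.family == "random-forest":
            return RandomForestClassifier(random_state=self.seed, **p)
        if self.family == "gradient-boosted-trees":
            return XGBClassifier(
                booster=p["booster"],
                learning_rate=p["learning_rate"],
                gamma=p["min_split_loss"],
                max_depth=p["max_depth"],
                sampling_method=p["sampling_method"],
                random_state=self.seed,
                n_jobs=1,
                eval_metric="logloss",
            )
        if self.family == "gaussian-naive-bayes":
            return GaussianNB(priors=p["priors"], var_smoothing=p["var_smoothing"])
        # neural-net: hidden layers as printed; the 1-unit sigmoid output is
        # implicit in the binary logistic output layer; standardization is
        # applied inside this family only.
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=tuple(p["hidden_units"]),
                        activation=p["activation"],
                        max_iter=p["epochs"],
                        random_state=self.seed,
                    ),
                ),
            ]
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with cancer (1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise FPScreenError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}


def train(spec: ClassifierSpec, train_rows: LabeledDataset):
    """Fit one classifier on the feature columns F1-F17.

    Requires both classes present and all features finite; returns the
    fitted model handle.
    """
    y = train_rows.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise FPScreenError("training set contains a single class")
    X = train_rows.X.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise FPScreenError("non-finite feature values in the training set")
    model = spec.build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at the printed epoch cap
        model.fit(X, y)
    return model


def evaluate(model, rows: LabeledDataset) -> ConfusionMatrix:
    """Score a fitted model; counts follow the cancer-positive orientation."""
    if len(rows) == 0:
        raise FPScreenError("cannot evaluate on an empty dataset")
    X = rows.X.to_numpy(dtype=float)
    expected = getattr(model, "n_features_in_", None)
    if expected is None and hasattr(model, "named_steps"):
        expected = model.named_steps["scale"].n_features_in_
    if expected is not None and X.shape[1] != expected:
        raise FPScreenError(
            f"feature-dimension mismatch: model expects {expected}, got {X.shape[1]}"
        )
    y = rows.y.to_numpy()
    pred = np.asarray(model.predict(X)).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from one confusion matrix.

    accuracy  = (TP+TN)/(TP+FP+TN+FN)
    precision = TP/(TP+FP)
    recall    = TP/(TP+FN)
    F1        = 2*precision*recall/(precision+recall)

    A zero denominator yields NaN (an explicit undefined sentinel, never a
    silent zero) and a warning is logged.
    """
    if cm.total == 0:
        raise FPScreenError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting NaN", name)
            return math.nan
        return num / den

    precision = _safe(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe(cm.tp, cm.tp + cm.fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        if not (math.isnan(precision) or math.isnan(recall)):
            logger.warning("F1 undefined (precision + recall = 0); reporting NaN")
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass
class FoldResult:
    """Held-out and training scores for one CV fold of one classifier."""

    fold: int
    holdout_cm: ConfusionMatrix
    holdout_metrics: dict[str, float]
    train_cm: ConfusionMatrix
    train_metrics: dict[str, float]
    fit_seconds: float


@dataclass
class ClassifierReport:
    family: str
    spec: dict[str, Any]
    folds: list[FoldResult]
    validation_cm: ConfusionMatrix | None
    validation_metrics: dict[str, float] | None
    fit_seconds: float
    predict_seconds: float

    def mean_fold_metric(self, name: str, which: str = "holdout") -> float:
        vals = [
            (f.holdout_metrics if which == "holdout" else f.train_metrics)[name]
            for f in self.folds
        ]
        return float(np.mean(vals))


@dataclass
class EvaluationReport:
    """Per-classifier fold and validation results for one experiment."""

    classifiers: list[ClassifierReport]
    fold_score: str = "holdout"  # reporting convention for the flat table

    def best_classical(self, metric: str = "accuracy", on: str = "validation") -> ClassifierReport:
        candidates = [c for c in self.classifiers if c.family in CLASSICAL_FAMILIES]
        if not candidates:
            raise FPScreenError("no classical classifier in the report")
        if on == "validation":
            return max(candidates, key=lambda c: c.validation_metrics[metric])
        return max(candidates, key=lambda c: c.mean_fold_metric(metric, which=on))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"fold_score": self.fold_score, "classifiers": []}
        for c in self.classifiers:
            out["classifiers"].append(
                {
                    "family": c.family,
                    "spec": c.spec,
                    "timing": {"fit_seconds": c.fit_seconds, "predict_seconds": c.predict_seconds},
                    "folds": [
                        {
                            "fold": f.fold,
                            "holdout": {"confusion": f.holdout_cm.as_dict(), **f.holdout_metrics},
                            "train": {"confusion": f.train_cm.as_dict(), **f.train_metrics},
                        }
                        for f in c.folds
                    ],
                    "validation": None
                    if c.validation_cm is None
                    else {"confusion": c.validation_cm.as_dict(), **c.validation_metrics},
                }
            )
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_table(self) -> pd.DataFrame:
        """Flat table mirroring the study's results layout (one row per fold
        plus a Validation row per classifier)."""
        rows = []
        for c in self.classifiers:
            for f in c.folds:
                m = f.holdout_metrics if self.fold_score == "holdout" else f.train_metrics
                rows.append(
                    {
                        "Classifier": c.family,
                        "Fold": f.fold + 1,
                        "Accuracy": m["accuracy"],
                        "Precision": m["precision"],
                        "Recall": m["recall"],
                        "F1-score": m["f1"],
                    }
                )
            if c.validation_metrics is not None:
                rows.append(
                    {
                        "Classifier": c.family,
                        "Fold": "Validation",
                        "Accuracy": c.validation_metrics["accuracy"],
                        "Precision": c.validation_metrics["precision"],
                        "Recall": c.validation_metrics["recall"],
                        "F1-score": c.validation_metrics["f1"],
                    }
                )
        return pd.DataFrame(rows)


def run_experiment(
    ds: LabeledDataset,
    plan: FoldPlan,
    specs: list[ClassifierSpec],
    validation: LabeledDataset | None = None,
) -> EvaluationReport:
    """Run the full CV protocol for every classifier spec.

    For each spec: k fold results (model trained on k-1 folds, scored both on
    the held-out fold and on its own training folds), then one validation
    result from a model retrained on all training rows and scored on the
    held-out validation split.  Wall-clock fit/predict times are logged but
    never asserted.
    """
    if not set(plan.train_indices).issubset(set(ds.frame.index)):
        raise FPScreenError("fold plan is inconsistent with the dataset")
    reports: list[ClassifierReport] = []
    for spec in specs:
        folds: list[FoldResult] = []
        for fold_id in range(plan.k):
            rest, held = plan.fold_split(fold_id)
            t0 = time.perf_counter()
            model = train(spec, ds.subset(rest))
            dt = time.perf_counter() - t0
            hold_cm = evaluate(model, ds.subset(held))
            train_cm = evaluate(model, ds.subset(rest))
            folds.append(
                FoldResult(
                    fold=fold_id,
                    holdout_cm=hold_cm,
                    holdout_metrics=metrics(hold_cm),
                    train_cm=train_cm,
                    train_metrics=metrics(train_cm),
                    fit_seconds=dt,
                )
            )
        t0 = time.perf_counter()
        full_model = train(spec, ds.subset(plan.train_indices))
        fit_s = time.perf_counter() - t0
        val_cm = None
        val_metrics = None
        predict_s = 0.0
        if validation is not None and len(validation):
            t0 = time.perf_counter()
            val_cm = evaluate(full_model, validation)
            predict_s = time.perf_counter() - t0
            val_metrics = metrics(val_cm)
        logger.info(
            "%s: fit %.3fs predict %.3fs validation accuracy %s",
            spec.family, fit_s, predict_s,
            "n/a" if val_metrics is None else f"{val_metrics['accuracy']:.3f}",
        )
        reports.append(
            ClassifierReport(
                family=spec.family,
                spec={"hyperparameters": spec.resolved(), "seed": spec.seed},
                folds=folds,
                validation_cm=val_cm,
                validation_metrics=val_metrics,
                fit_seconds=fit_s,
                predict_seconds=predict_s,
            )
        )
    return EvaluationReport(classifiers=reports)
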