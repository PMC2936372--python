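"""RBF-kernel multiclass SVM training, grid search and evaluation metrics.

Training follows the standard myoelectric-classification recipe: each of
the 24 features is affinely rescaled so its training range becomes [-1, 1]
(the RBF kernel K(x, x') = exp(-gamma ||x - x'||^2) needs commensurate
feature scales), then a one-vs-one SVM is fitted with (C, gamma) chosen by
stratified 8-fold cross-validated grid search.  Ties in CV accuracy break
toward smaller C, then smaller gamma — the least complex model.

Besides overall and macro-averaged accuracy, :func:`adjacent_tolerant_accuracy`
scores a confusion matrix while forgiving confusions between adjacent torque
levels of the same direction — the error mode that matters least to an
assistive device, since it only mis-doses, never mis-directs, the support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import ClassConfig, Direction
from .features import feature_columns

MODEL_FORMAT_VERSION = 1


def _default_c_grid() -> tuple[float, ...]:
    return (1.0, *[float(v) for v in range(10, 101, 10)])


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(round(0.1 + 0.2 * k, 10) for k in range(8))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter search space: C in {1, 10, 20, ..., 100}, gamma in
    {0.1, 0.3, ..., 1.5}, 8-fold stratified CV.

    The lattice spans two decades of regularization strength and the whole
    useful RBF-width range for features scaled to [-1, 1], with plausible
    optima (C around 50-90, gamma around 0.7-1.0) strictly interior; a finer
    lattice multiplies search cost without moving the selected model on this
    family of feature distributions."""

    c_values: tuple[float, ...] = field(default_factory=_default_c_grid)
    gamma_values: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    folds: int = 8

    def __post_init__(self) -> None:
        if not self.c_values or min(self.c_values) <= 0:
            raise ValueError("all C candidates must be positive")
        if not self.gamma_values or min(self.gamma_values) <= 0:
            raise ValueError("all gamma candidates must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class FeatureScaler:
    """Per-feature affine map sending the training range to [-1, 1];
    zero-range features map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.lo) / safe - 1.0
        out[..., span == 0] = 0.0
        return out


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on empty data")
    return FeatureScaler(lo=X.min(axis=0), hi=X.max(axis=0))


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


@dataclass
class TrainedModel:
    """Fitted scaler + one-vs-one RBF-SVM with its CV diagnostics."""

    scaler: FeatureScaler
    svc: SVC
    C: float
    gamma: float
    cv_accuracy: float
    classes: np.ndarray
    cv_table: pd.DataFrame  # one row per (C, gamma) with mean CV accuracy
    folds: int
    seed: int | None
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(np.asarray(X, dtype=float)))


def _as_xy(features, labels=None, feature_names=None):
    """Accept a feature DataFrame (with label column) or plain arrays."""
    if isinstance(features, pd.DataFrame):
        names = feature_names or [c for c in features.columns
                                  if c not in ("label", "source", "start_sample")]
        X = features[names].to_numpy(float)
        y = features["label"].to_numpy() if labels is None else np.asarray(labels)
        return X, y, list(names)
    X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels required when features is an array")
    return X, np.asarray(labels), feature_names


def grid_search_train(
    features,
    labels=None,
    grid: GridSpec = GridSpec(),
    seed: int | None = 0,
) -> TrainedModel:
    """Grid-search (C, gamma) by stratified k-fold CV and refit on all data.

    ``features`` may be a feature DataFrame carrying a ``label`` column or a
    plain (n, d) array with ``labels``.  The scaler is fitted on the full
    training set; fold assignment is shuffled under ``seed``, so a fixed
    seed gives identical folds and an identical chosen (C, gamma).
    """
    X, y, names = _as_xy(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < grid.folds:
        raise ValueError(
            f"every class needs >= {grid.folds} members for {grid.folds}-fold CV; "
            f"smallest has {counts.min()}"
        )
    scaler = fit_scaler(X)
    Xs = scaler.transform(X)

    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y))

    records = []
    best = None  # (accuracy, C, gamma); strict > keeps smallest C then gamma
    for C in sorted(grid.c_values):
        for gamma in sorted(grid.gamma_values):
            correct = total = 0
            for tr, va in folds:
                clf = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=256)
                clf.fit(Xs[tr], y[tr])
                correct += int(np.sum(clf.predict(Xs[va]) == y[va]))
                total += len(va)
            acc = correct / total
            records.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, C, gamma)

    cv_acc, C, gamma = best
    svc = SVC(C=C, kernel="rbf", gamma=gamma, cache_size=256)
    svc.fit(Xs, y)
    return TrainedModel(
        scaler=scaler, svc=svc, C=C, gamma=gamma, cv_accuracy=cv_acc,
        classes=classes, cv_table=pd.DataFrame.from_records(records),
        folds=grid.folds, seed=seed, feature_names=names,
    )


@dataclass
class EvaluationReport:
    overall_accuracy: float
    macro_accuracy: float  # mean of per-class recalls
    confusion: pd.DataFrame  # rows: true class, columns: predicted


def evaluate(model: TrainedModel, features, labels=None) -> EvaluationReport:
    """Overall accuracy, macro per-class accuracy and the confusion matrix."""
    X, y, _ = _as_xy(features, labels, model.feature_names)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    unseen = set(np.unique(y)) - set(model.classes.tolist())
    if unseen:
        raise ValueError(f"test labels never seen in training: {sorted(unseen)}")
    pred = model.predict(X)
    ids = list(model.classes)
    cm = _sk_confusion(y, pred, labels=ids)
    confusion = pd.DataFrame(cm, index=ids, columns=ids)
    overall = float(accuracy_score(y, pred))
    row_sums = cm.sum(axis=1)
    present = row_sums > 0
    recalls = np.diag(cm)[present] / row_sums[present]
    return EvaluationReport(
        overall_accuracy=overall,
        macro_accuracy=float(np.mean(recalls)),
        confusion=confusion,
    )


def _adjacent_pairs(config: ClassConfig) -> set[tuple[int, int]]:
    """Unordered pairs of class ids one configured level step apart (rest is
    adjacent to every direction's lowest configured level)."""
    pairs: set[tuple[int, int]] = set()
    rest = config.rest_class().class_id
    for direction in (Direction.FLEXION, Direction.EXTENSION,
                      Direction.ULNAR, Direction.RADIAL):
        try:
            ladder = config.classes_for(direction)
        except KeyError:
            continue
        ids = [rest] + [c.class_id for c in ladder]
        pairs.update(zip(ids, ids[1:]))
    return {tuple(sorted(p)) for p in pairs}


def adjacent_tolerant_accuracy(confusion: pd.DataFrame, config: ClassConfig) -> float:
    """Accuracy counting adjacent-level, same-direction confusions as correct.

    Always >= the plain overall accuracy of the same confusion matrix;
    direction-crossing errors are never forgiven.
    """
    total = int(confusion.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    pairs = _adjacent_pairs(config)
    ok = 0
    for true_id in confusion.index:
        for pred_id in confusion.columns:
            n = int(confusion.loc[true_id, pred_id])
            if n == 0:
                continue
            if true_id == pred_id or tuple(sorted((int(true_id), int(pred_id)))) in pairs:
                ok += n
    return ok / total


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (joblib archive with a format-version tag)."""
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "scaler_lo": model.scaler.lo, "scaler_hi": model.scaler.hi,
        "svc": model.svc, "C": model.C, "gamma": model.gamma,
        "cv_accuracy": model.cv_accuracy, "classes": model.classes,
        "cv_table": model.cv_table, "folds": model.folds, "seed": model.seed,
        "feature_names": model.feature_names,
    }, path)


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return TrainedModel(
        scaler=FeatureScaler(lo=blob["scaler_lo"], hi=blob["scaler_hi"]),
        svc=blob["svc"], C=blob["C"], gamma=blob["gamma"],
        cv_accuracy=blob["cv_accuracy"], classes=blob["classes"],
        cv_table=blob["cv_table"], folds=blob["folds"], seed=blob["seed"],
        feature_names=blob["feature_names"],
    )
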