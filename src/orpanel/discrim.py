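"""Odor discrimination from panel response vectors.

Each trial is the 32-dimensional vector of scalar responses (31 ORs plus
the vector control) for one replicate of one odorant on one day.  Odors are
visualized with t-SNE and discriminated with a random forest (500 trees,
sqrt-feature subsets, majority vote) or linear discriminant analysis, always
under a cross-day protocol: the classifier trains on one day's trials and is
scored on a different day's trials, so accuracy reflects day-to-day
generalization rather than within-run memorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE

from .errors import InsufficientDataError, ParameterError, StructureError
from .traceproc import ResponseMatrix

__all__ = [
    "TrialTable", "ClassifierReport", "EmbeddingResult",
    "trials_from_matrix", "tsne_embed", "train_classifier", "evaluate",
    "cross_day_report",
]

METHODS = ("random_forest", "lda")


@dataclass
class TrialTable:
    """Trial design matrix: rows are (odorant, day, replicate) trials."""

    X: np.ndarray                 # n_trials x panel_size
    labels: np.ndarray            # odorant per trial
    days: np.ndarray
    replicates: np.ndarray
    feature_names: list[str]      # panel order, vector control included

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or len(self.labels) != self.X.shape[0]:
            raise StructureError("trial matrix and labels disagree")
        if not np.all(np.isfinite(self.X)):
            raise StructureError("trial vectors must be finite")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


def trials_from_matrix(matrix: ResponseMatrix) -> TrialTable:
    """Pivot a tidy response matrix into replicate-level trial vectors.

    No replicate averaging: with triplicates there are three trials per
    odorant per day.  Feature order follows the panel order of the matrix.
    """
    wide = matrix.tidy.pivot_table(
        index=["odorant_id", "day", "replicate"], columns="or_id",
        values="value", aggfunc="first",
    ).reindex(columns=matrix.or_ids)
    if wide.isna().any().any():
        raise StructureError("incomplete trials: some receptor values are missing")
    idx = wide.index.to_frame(index=False)
    return TrialTable(
        X=wide.to_numpy(dtype=float),
        labels=idx["odorant_id"].to_numpy(),
        days=idx["day"].to_numpy(),
        replicates=idx["replicate"].to_numpy(),
        feature_names=list(matrix.or_ids),
    )


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray       # n_trials x 2
    labels: np.ndarray
    perplexity: float
    seed: int
    params: dict = field(default_factory=dict)


def tsne_embed(trials: TrialTable, perplexity: float = 10.0, seed: int = 0) -> EmbeddingResult:
    """2-D t-SNE of trial vectors (Euclidean on raw responses, perplexity 10)."""
    if perplexity >= trials.n_trials:
        raise ParameterError(
            f"perplexity ({perplexity}) must be < number of trials ({trials.n_trials})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(trials.X)
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        labels=trials.labels.copy(),
        perplexity=perplexity, seed=seed,
        params={"init": "pca", "metric": "euclidean", "n_components": 2},
    )


def train_classifier(trials: TrialTable, method: str = "random_forest", seed: int = 0):
    """Fit the discrimination model on one day's trials."""
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}")
    classes, counts = np.unique(trials.labels, return_counts=True)
    if classes.size < 2:
        raise InsufficientDataError("need >= 2 odor classes to train")
    if counts.min() < 2:
        raise InsufficientDataError("need >= 2 trials per class")
    if method == "random_forest":
        model = RandomForestClassifier(
            n_estimators=500, max_features="sqrt", max_depth=None,
            bootstrap=True, random_state=seed,
        )
    else:
        model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(trials.X, trials.labels)
    return model


@dataclass
class ClassifierReport:
    method: str
    predictions: pd.DataFrame     # odorant, day, replicate, predicted
    confusion: pd.DataFrame       # true x predicted counts
    accuracy_pct: float
    train_days: tuple[str, ...]
    test_days: tuple[str, ...]
    seed: int

    @classmethod
    def from_predictions(cls, y_true, y_pred, *, method: str,
                         days=None, replicates=None,
                         train_days=(), test_days=(), seed: int = 0) -> "ClassifierReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.size == 0:
            raise InsufficientDataError("empty test set")
        if y_true.size != y_pred.size:
            raise StructureError("prediction/label length mismatch")
        classes = sorted(set(y_true) | set(y_pred))
        confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(y_true, y_pred):
            confusion.loc[t, p] += 1
        accuracy = 100.0 * np.trace(confusion.to_numpy()) / y_true.size
        predictions = pd.DataFrame({
            "odorant_id": y_true,
            "day": days if days is not None else [""] * y_true.size,
            "replicate": replicates if replicates is not None else np.arange(1, y_true.size + 1),
            "predicted": y_pred,
        })
        return cls(method=method, predictions=predictions, confusion=confusion,
                   accuracy_pct=float(accuracy),
                   train_days=tuple(train_days), test_days=tuple(test_days), seed=seed)


def evaluate(model, trials: TrialTable, *, method: str = "random_forest",
             train_days=(), seed: int = 0) -> ClassifierReport:
    """Score a fitted model on held-out trials."""
    if trials.X.shape[1] != getattr(model, "n_features_in_", trials.X.shape[1]):
        raise StructureError("test trials do not match the model's panel dimension")
    if trials.n_trials == 0:
        raise InsufficientDataError("empty test set")
    y_pred = model.predict(trials.X)
    return ClassifierReport.from_predictions(
        trials.labels, y_pred, method=method,
        days=trials.days, replicates=trials.replicates,
        train_days=tuple(train_days), test_days=tuple(sorted(set(trials.days))),
        seed=seed,
    )


def cross_day_report(
    train_matrix: ResponseMatrix,
    test_matrix: ResponseMatrix,
    method: str = "random_forest",
    seed: int = 0,
) -> ClassifierReport:
    """Train on one day's response matrix, score on another day's.

    Raises if the two matrices share any day label: cross-day accuracy is
    only meaningful for disjoint sessions.
    """
    train = trials_from_matrix(train_matrix)
    test = trials_from_matrix(test_matrix)
    if set(train.days) & set(test.days):
        raise ParameterError("train and test trials must come from disjoint days")
    if train.feature_names != test.feature_names:
        raise StructureError("train and test panels differ")
    model = train_classifier(train, method=method, seed=seed)
    return evaluate(model, test, method=method,
                    train_days=tuple(sorted(set(train.days))), seed=seed)
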