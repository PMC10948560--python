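"""Four-class lesion classification from profile diagonals.

A second-order polynomial support-vector machine (kernel scale 1, offset 0,
box constraint 1, one-vs-one multiclass reduction, SMO-style solver) is
trained on the seven scaled features and applied to the diagonals of
received DPs. Training records the stratified five-fold cross-validation
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import ParameterError
from .features import FEATURE_NAMES, FeatureScaler
from .profile import DP

_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    """Fitted classifier plus the scaler it expects its inputs to share."""

    svc: SVC
    labels: list[str]
    cv_accuracy: float
    seed: int
    scaler: FeatureScaler | None = None
    per_class_recall: dict[str, float] = field(default_factory=dict)


def _make_svc() -> SVC:
    # quadratic polynomial kernel, scale (gamma) 1, offset (coef0) 0, C = 1
    return SVC(kernel="poly", degree=2, gamma=1.0, coef0=0.0, C=1.0)


def train(features: pd.DataFrame | np.ndarray,
          labels: np.ndarray | list[str] | None = None, seed: int = 0,
          scaler: FeatureScaler | None = None, n_folds: int = 5) -> TrainedModel:
    """Fit the SVM and record its stratified cross-validated accuracy.

    ``features`` is either a table with the canonical feature columns and a
    ``label`` column, or a plain (n, 7) array with ``labels`` given
    separately. Values are expected already min-max scaled to [0, 1].
    """
    if isinstance(features, pd.DataFrame):
        if labels is None:
            labels = features["label"].to_numpy()
        x = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("need at least two classes to train")
    if counts.min() < n_folds:
        raise ParameterError(
            f"need at least {n_folds} samples per class for {n_folds}-fold CV")

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_make_svc(), x, y, cv=cv)
    svc = _make_svc().fit(x, y)

    pred = svc.predict(x)
    recall = {c: float(np.mean(pred[y == c] == c)) for c in classes}
    return TrainedModel(svc=svc, labels=[str(c) for c in classes],
                        cv_accuracy=float(scores.mean()), seed=seed,
                        scaler=scaler, per_class_recall=recall)


def predict_features(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return model.svc.predict(x)


def predict(model: TrainedModel, dps: list[DP]) -> list[str]:
    """Classify each DP from its seven diagonal values."""
    if not dps:
        return []
    rows = []
    for dp in dps:
        mat = np.asarray(dp.matrix, dtype=float)
        if mat.shape != (7, 7):
            raise ParameterError("malformed DP: expected a 7x7 matrix")
        rows.append(np.diag(mat))
    return [str(label) for label in predict_features(model, np.array(rows))]


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"version": _FORMAT_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    doc = joblib.load(path)
    if doc.get("version") != _FORMAT_VERSION:
        raise ParameterError("unsupported model container version")
    return doc["model"]
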