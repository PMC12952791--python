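"""Tree-ensemble behavior classifiers over windowed pose features.

Training consumes sparse frame labels: unlabeled frames are simply excluded.
Cross-validation folds are grouped by video so frames of one video never span
the train/test boundary.

Algorithm names map to scikit-learn ensembles: ``random_forest`` ->
RandomForestClassifier, ``gradient_boost`` -> GradientBoostingClassifier,
``xgboost`` -> HistGradientBoostingClassifier (a histogram-based gradient
boosting machine of the same family; the eponymous external library is not a
dependency).  All run with their library-default hyperparameters unless
overridden via ``params``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)

from .annotations import BEHAVIOR, NOT_BEHAVIOR, Ethogram
from .features import FeatureMatrix
from . import metrics as _metrics

__all__ = [
    "ALGORITHMS",
    "MIN_LABELED_FRAMES",
    "MIN_VIDEOS",
    "ClassifierModel",
    "TrainingError",
    "train",
    "cross_validate",
    "predict",
    "export_classifier",
    "import_classifier",
]

ALGORITHMS = ("random_forest", "gradient_boost", "xgboost")

#: minimum labeled data required to train
MIN_LABELED_FRAMES = 100
MIN_VIDEOS = 2

_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when the training data violate the minimum-data contract."""


def _make_estimator(algorithm: str, seed: int, params: dict | None):
    params = dict(params or {})
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "gradient_boost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "xgboost":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ClassifierModel:
    """A trained behavior classifier plus the metadata needed to reuse it."""

    algorithm: str
    window_size: int
    feature_names: tuple[str, ...]
    behavior_name: str
    estimator: object
    training_summary: dict = field(default_factory=dict)
    format_version: int = _FORMAT_VERSION

    def feature_importances(self) -> pd.Series | None:
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            return None
        return pd.Series(imp, index=list(self.feature_names)).sort_values(ascending=False)


def _collect_training_rows(
    datasets: Sequence[tuple[FeatureMatrix, Ethogram]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack labeled, valid frames from every (features, labels) pair."""
    xs, ys, groups = [], [], []
    names = None
    for vid, (fm, eth) in enumerate(datasets):
        if fm.n_frames != eth.n_frames:
            raise ValueError(f"video {vid}: features and labels disagree on frame count")
        if names is None:
            names = fm.feature_names
        elif fm.feature_names != names:
            raise ValueError(f"video {vid}: feature names differ from video 0")
        keep = eth.labeled_mask() & fm.valid_mask
        keep &= np.isfinite(fm.values).all(axis=1)
        xs.append(fm.values[keep])
        ys.append((eth.labels[keep] == BEHAVIOR).astype(np.int8))
        groups.append(np.full(int(keep.sum()), vid))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(groups)


def train(
    datasets: Sequence[tuple[FeatureMatrix, Ethogram]],
    algorithm: str = "random_forest",
    seed: int = 0,
    params: dict | None = None,
    balance_classes: bool = False,
) -> ClassifierModel:
    """Fit a behavior classifier from sparse frame labels.

    Requires at least :data:`MIN_LABELED_FRAMES` labeled frames across at
    least :data:`MIN_VIDEOS` videos, with both classes present.  With
    ``balance_classes`` the fit uses inverse-class-frequency sample weights.
    """
    if len(datasets) < MIN_VIDEOS:
        raise TrainingError(
            f"training requires at least {MIN_VIDEOS} videos, got {len(datasets)}"
        )
    X, y, groups = _collect_training_rows(datasets)
    n_videos_labeled = np.unique(groups).size
    if n_videos_labeled < MIN_VIDEOS:
        raise TrainingError(
            f"labeled frames span {n_videos_labeled} videos; minimum is {MIN_VIDEOS}"
        )
    if X.shape[0] < MIN_LABELED_FRAMES:
        raise TrainingError(
            f"{X.shape[0]} labeled frames; minimum is {MIN_LABELED_FRAMES}"
        )
    if np.unique(y).size < 2:
        raise TrainingError("training labels contain a single class")
    est = _make_estimator(algorithm, seed, params)
    sample_weight = None
    if balance_classes:
        freq = np.bincount(y, minlength=2) / y.size
        sample_weight = 1.0 / freq[y]
    est.fit(X, y, sample_weight=sample_weight)
    fm0, eth0 = datasets[0]
    return ClassifierModel(
        algorithm=algorithm,
        window_size=fm0.window_size,
        feature_names=fm0.feature_names,
        behavior_name=eth0.behavior_name,
        estimator=est,
        training_summary={
            "n_labeled_frames": int(X.shape[0]),
            "n_videos": int(n_videos_labeled),
            "behavior_fraction": float(y.mean()),
            "seed": int(seed),
        },
    )


def predict(model: ClassifierModel, features: FeatureMatrix) -> Ethogram:
    """Predict a binary ethogram (with probabilities) for one video.

    Frames flagged invalid (or containing non-finite features) are predicted
    not-behavior with probability NaN.  The label is behavior iff the
    predicted probability exceeds 0.5.
    """
    if features.feature_names != model.feature_names:
        missing = set(model.feature_names) - set(features.feature_names)
        extra = set(features.feature_names) - set(model.feature_names)
        raise ValueError(
            f"feature names do not match the classifier: missing={sorted(missing)[:5]}, "
            f"unexpected={sorted(extra)[:5]}"
        )
    ok = features.valid_mask & np.isfinite(features.values).all(axis=1)
    probs = np.full(features.n_frames, np.nan)
    if ok.any():
        probs[ok] = model.estimator.predict_proba(features.values[ok])[:, 1]
    labels = np.where(np.nan_to_num(probs, nan=0.0) > 0.5, BEHAVIOR, NOT_BEHAVIOR)
    return Ethogram(
        labels,
        probabilities=probs,
        fps=features.fps,
        behavior_name=model.behavior_name,
        source=f"classifier:{model.algorithm}",
    )


def _grouped_folds(groups: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle videos and deal them into k folds; returns per-fold row masks."""
    videos = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(videos)
    folds = [order[i::k] for i in range(k)]
    return [np.isin(groups, f) for f in folds]


def cross_validate(
    datasets: Sequence[tuple[FeatureMatrix, Ethogram]],
    algorithm: str = "random_forest",
    k: int = 5,
    seed: int = 0,
    params: dict | None = None,
) -> pd.DataFrame:
    """k-fold cross-validation with folds grouped by video.

    Returns a per-fold table of accuracy, F1, and AUROC with a mean/sd
    summary available via ``DataFrame.attrs['summary']``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(datasets) < k:
        raise ValueError(f"{len(datasets)} videos cannot form {k} grouped folds")
    X, y, groups = _collect_training_rows(datasets)
    rows = []
    for fold, test_mask in enumerate(_grouped_folds(groups, k, seed)):
        est = _make_estimator(algorithm, seed, params)
        est.fit(X[~test_mask], y[~test_mask])
        if np.unique(y[~test_mask]).size < 2 or not test_mask.any():
            raise TrainingError(f"fold {fold}: degenerate train/test split")
        p = est.predict_proba(X[test_mask])[:, 1]
        yhat = (p > 0.5).astype(int)
        yt = y[test_mask]
        ref = Ethogram(yt.astype(np.int8))
        pred = Ethogram(yhat.astype(np.int8))
        fc = _metrics.frame_metrics(ref, pred)
        if np.unique(yt).size == 2:
            auroc = _metrics.roc_metrics(p, ref)["auroc"]
        else:
            auroc = np.nan
        rows.append(
            {"fold": fold, "accuracy": fc.accuracy, "f1": fc.f1, "auroc": auroc}
        )
    table = pd.DataFrame(rows)
    table.attrs["summary"] = {
        c: {"mean": float(table[c].mean()), "sd": float(table[c].std())}
        for c in ("accuracy", "f1", "auroc")
    }
    return table


def export_classifier(model: ClassifierModel, path) -> str:
    """Serialize a classifier with its metadata to a single-file archive."""
    payload = {
        "format_version": model.format_version,
        "algorithm": model.algorithm,
        "window_size": model.window_size,
        "feature_names": list(model.feature_names),
        "behavior_name": model.behavior_name,
        "training_summary": model.training_summary,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    return str(path)


def import_classifier(path) -> ClassifierModel:
    """Load a classifier archive, validating version and metadata."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict):
        raise ValueError("not a classifier archive")
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {version!r}")
    required = ("algorithm", "window_size", "feature_names", "behavior_name", "estimator")
    missing = [kk for kk in required if payload.get(kk) is None]
    if missing:
        raise ValueError(f"archive missing metadata: {missing}")
    return ClassifierModel(
        algorithm=payload["algorithm"],
        window_size=int(payload["window_size"]),
        feature_names=tuple(payload["feature_names"]),
        behavior_name=payload["behavior_name"],
        estimator=payload["estimator"],
        training_summary=payload.get("training_summary", {}),
        format_version=version,
    )
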