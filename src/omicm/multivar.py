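"""Multivariate cohort analysis: UMAP embedding of the eight OMI variables
and a random-forest classifier separating healthy from diseased cells.

The forest uses 100 trees, unlimited depth and a minimum of 2 samples to
split; the 70/30 train/test split is stratified per class with test size
ceiling(n_class * 0.3), so e.g. 2235 cells split 1564/671 and 4990 split
3493/1497.  UMAP runs with n_neighbors 15, min_dist 0.1, cosine metric,
2 output components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.ensemble import RandomForestClassifier

from .cellquant import OMI_VARIABLES

__all__ = [
    "EmbeddingResult",
    "ClassifierReport",
    "split_counts",
    "umap_embed",
    "train_classifier",
    "roc_curve",
    "UMAP_DEFAULTS",
    "FOREST_DEFAULTS",
]

UMAP_DEFAULTS = {
    "n_neighbors": 15,
    "min_dist": 0.1,
    "metric": "cosine",
    "n_components": 2,
}

FOREST_DEFAULTS = {
    "n_estimators": 100,
    "max_depth": None,
    "min_samples_split": 2,
}


def split_counts(n_total: int, test_fraction: float = 0.3) -> tuple[int, int]:
    """Train/test sizes with test size = ceiling(n_total * test_fraction).

    A 1e-9 backoff before the ceiling guards against binary-float fuzz
    (4990 * 0.3 evaluates slightly above 1497).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    n_test = int(math.ceil(n_total * test_fraction - 1e-9))
    return n_total - n_test, n_test


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    params: dict
    seed: int


@dataclass
class ClassifierReport:
    """Evaluation of the two-class forest on the held-out split."""

    auc: float
    confusion: np.ndarray  # rows: true [neg, pos]; cols: predicted [neg, pos]
    accuracy: float
    precision: float
    recall: float
    importances: dict  # feature -> importance, summing to 1
    split: dict  # class label -> {"n_train": ..., "n_test": ...}
    seed: int
    config: dict = field(default_factory=lambda: dict(FOREST_DEFAULTS))
    positive_label: str = ""

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "importances": self.importances,
            "split": self.split,
            "seed": self.seed,
            "config": self.config,
            "positive_label": self.positive_label,
        }


def _feature_matrix(table: pd.DataFrame, features) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def umap_embed(
    table: pd.DataFrame,
    params: dict | None = None,
    seed: int = 0,
    features=OMI_VARIABLES,
) -> EmbeddingResult:
    """2-D UMAP embedding of the eight OMI variables, row-aligned."""
    p = dict(UMAP_DEFAULTS)
    p.update(params or {})
    X = _feature_matrix(table, features)
    if X.shape[0] < p["n_neighbors"] + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {p['n_neighbors'] + 1} rows, "
            f"got {X.shape[0]}"
        )
    import umap  # deferred: numba-jitted import is slow

    reducer = umap.UMAP(random_state=seed, **p)
    coords = np.asarray(reducer.fit_transform(X), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return EmbeddingResult(coordinates=coords, params=p, seed=seed)


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split obeying split_counts within each class."""
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        _, n_test = split_counts(idx.size, test_fraction)
        idx = rng.permutation(idx)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC threshold sweep and trapezoid AUC from binary labels + scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two label values, got {uniq.tolist()}")
    y = (labels == uniq.max()).astype(int)
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def train_classifier(
    table: pd.DataFrame,
    label_column: str = "line",
    positive_label: str | None = None,
    test_fraction: float = 0.3,
    seed: int = 0,
    features=OMI_VARIABLES,
    config: dict | None = None,
) -> ClassifierReport:
    """Train and evaluate the two-class random forest on OMI features.

    Stratified 70/30 split (per-class ceiling rounding on the test side),
    ROC from the positive-class vote fraction, confusion matrix at the
    0.5 vote threshold, importances normalized to sum 1.
    """
    if label_column not in table.columns:
        raise KeyError(f"unknown label column {label_column!r}")
    y_raw = table[label_column].to_numpy()
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[-1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not present")
    counts = {c: int((y_raw == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 rows, got {counts}")

    X = _feature_matrix(table, features)
    y = (y_raw == positive_label).astype(int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y_raw, test_fraction, rng)

    cfg = dict(FOREST_DEFAULTS)
    cfg.update(config or {})
    forest = RandomForestClassifier(random_state=seed, **cfg)
    forest.fit(X[train_idx], y[train_idx])

    votes = forest.predict_proba(X[test_idx])[:, list(forest.classes_).index(1)]
    y_test = y[test_idx]
    _, _, auc = roc_curve(votes, y_test)
    pred = (votes >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    confusion = np.array([[tn, fp], [fn, tp]])
    n_test = y_test.size
    # per-tree importances are normalized by construction, so these sum to 1
    importances = {
        f: float(v) for f, v in zip(features, forest.feature_importances_)
    }
    split = {
        str(c): {
            "n_train": int(np.sum(y_raw[train_idx] == c)),
            "n_test": int(np.sum(y_raw[test_idx] == c)),
        }
        for c in classes
    }
    return ClassifierReport(
        auc=auc,
        confusion=confusion,
        accuracy=(tp + tn) / n_test,
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        importances=importances,
        split=split,
        seed=seed,
        config=cfg,
        positive_label=str(positive_label),
    )
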