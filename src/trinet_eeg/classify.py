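"""Linear-SVM classification of connection features and weight ranking.

Subjects are classified impaired vs control from their band-wise
connectivity vectors (276 features for the 24-ROI atlas) with a linear
support vector machine (C = 1), features standardized to zero mean / unit
variance. Performance is assessed by stratified k-fold cross-validation
(default 10-fold) with standardization fitted inside each training fold;
accuracy, sensitivity and specificity are pooled over held-out
predictions, with "impaired" the positive class.

Connection importance is the absolute value of the linear-SVM coefficient
from a single fit on the full standardized table; features are ranked by
|weight| descending (ties broken by fixed feature order) and the top 5%
(floor, i.e. 13 of 276) form the reported top set. A per-fold mean-|weight|
ranking is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .atlas import Atlas

POSITIVE_CLASS = "impaired"
SVM_C = 1.0


@dataclass
class FeatureTable:
    """Subjects x connection-features design with group labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    band: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be subjects x features")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match subject count")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match feature count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values; exclude outliers first")
        if np.unique(self.y).size != 2:
            raise ValueError("expected exactly two classes")


@dataclass
class ClassifierReport:
    """Cross-validated performance plus the ranked connection weights."""

    accuracy: float
    sensitivity: float
    specificity: float
    band: str | None
    k_folds: int
    seed: int | None
    fold_assignments: np.ndarray
    ranked_features: list[str]
    ranked_weights: np.ndarray
    top_set: list[str]
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "confusion": self.confusion,
            "top_set": self.top_set,
        }


def _svm():
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=SVM_C))


def crossval_svm(ft: FeatureTable, k_folds: int = 10, seed: int | None = 0,
                 positive: str = POSITIVE_CLASS, top_frac: float = 0.05,
                 rank_mode: str = "full_fit") -> ClassifierReport:
    """Stratified k-fold CV metrics plus full-fit weight ranking."""
    classes = np.unique(ft.y)
    if positive not in classes:
        positive = classes[0]
    counts = {c: int((ft.y == c).sum()) for c in classes}
    if min(counts.values()) < k_folds:
        raise ValueError(
            f"smallest class ({min(counts.values())}) cannot populate "
            f"{k_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty(ft.y.shape, dtype=ft.y.dtype)
    folds = np.empty(ft.y.shape[0], dtype=int)
    for f, (tr, te) in enumerate(skf.split(ft.X, ft.y)):
        model = _svm().fit(ft.X[tr], ft.y[tr])
        pred[te] = model.predict(ft.X[te])
        folds[te] = f

    pos = ft.y == positive
    tp = int(np.sum(pred[pos] == positive))
    fn = int(pos.sum()) - tp
    tn = int(np.sum(pred[~pos] != positive))
    fp = int((~pos).sum()) - tn
    n = ft.y.size
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")

    names, weights, top = rank_weights(ft, top_frac=top_frac, mode=rank_mode,
                                       k_folds=k_folds, seed=seed)
    return ClassifierReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        band=ft.band, k_folds=k_folds, seed=seed, fold_assignments=folds,
        ranked_features=names, ranked_weights=weights, top_set=top,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp,
                   "positive_class": str(positive)},
    )


def rank_weights(ft: FeatureTable, top_frac: float = 0.05,
                 mode: str = "full_fit", k_folds: int = 10,
                 seed: int | None = 0) -> tuple[list[str], np.ndarray, list[str]]:
    """Features ranked by |linear-SVM coefficient|, and the top set.

    ``mode="full_fit"`` ranks from one fit on the whole standardized table;
    ``mode="fold_mean"`` averages |coefficients| over CV training folds.
    Ties break by the fixed feature order. ``top_frac=0.05`` on 276
    features yields floor(0.05 * 276) = 13.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    if mode == "full_fit":
        model = _svm().fit(ft.X, ft.y)
        absw = np.abs(model[-1].coef_.ravel())
    elif mode == "fold_mean":
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        ws = [
            np.abs(_svm().fit(ft.X[tr], ft.y[tr])[-1].coef_.ravel())
            for tr, _ in skf.split(ft.X, ft.y)
        ]
        absw = np.mean(ws, axis=0)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    order = np.argsort(-absw, kind="stable")  # stable sort -> ties by feature order
    ranked_names = [ft.feature_names[i] for i in order]
    ranked_w = absw[order]
    k = max(int(np.floor(top_frac * len(ranked_names))), 1)
    return ranked_names, ranked_w, ranked_names[:k]


def network_annotate(features: list[str], atlas: Atlas) -> dict[tuple[str, str], int]:
    """Count connections per unordered network pair (e.g. ('SN', 'VN'))."""
    counts: dict[tuple[str, str], int] = {}
    for name in features:
        key = atlas.network_pair(name)
        counts[key] = counts.get(key, 0) + 1
    return counts
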