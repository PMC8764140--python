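"""Class balancing, splitting, and the three grid-searched classifiers.

The protocol: the site set is split 80/20 stratified by class; random
undersampling balances the *training* side only to exactly 1:1 (the test set
stays imbalanced); hyperparameters are chosen by 5-fold cross-validation on
the balanced training matrix via exhaustive grid search.

Grids follow the study design: SVM (RBF) with C in {2^0..2^10} and gamma in
{2^-10..2^0}; random forest with tree counts {1400, 1600, ..., 2400}; logistic
regression trained by SGD on the cross-entropy loss with a single default
configuration and a 0.5 decision cutoff.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.svm import SVC

from .evaluation import confusion_at_cutoff, compute_metrics, roc_auc
from .sequence_encoders import FeatureMatrix

MODEL_KINDS = ("svm_rbf", "random_forest", "logistic_regression")

SVM_C_GRID = tuple(2.0 ** k for k in range(0, 11))
SVM_GAMMA_GRID = tuple(2.0 ** k for k in range(-10, 1))
RF_TREE_GRID = (1400, 1600, 1800, 2000, 2200, 2400)


@dataclass
class ModelSpec:
    """Classifier kind, hyperparameter grid, decision cutoff and seed."""

    kind: str
    grid: dict[str, tuple] = field(default_factory=dict)
    cutoff: float = 0.5
    seed: int = 0
    objective: str = "auc"  # or "acc"

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        if self.objective not in ("auc", "acc"):
            raise ValueError(f"objective must be 'auc' or 'acc', got {self.objective!r}")
        defaults = {
            "svm_rbf": {"C": SVM_C_GRID, "gamma": SVM_GAMMA_GRID},
            "random_forest": {"n_estimators": RF_TREE_GRID},
            "logistic_regression": {},
        }[self.kind]
        for key, vals in defaults.items():
            self.grid.setdefault(key, vals)
        for key, vals in self.grid.items():
            if len(tuple(vals)) == 0:
                raise ValueError(f"empty grid for parameter {key!r}")
            self.grid[key] = tuple(vals)

    def grid_points(self) -> list[dict]:
        """Grid points in documented iteration order (each axis ascending)."""
        if self.kind == "svm_rbf":
            return [
                {"C": c, "gamma": g}
                for c in sorted(self.grid["C"])
                for g in sorted(self.grid["gamma"])
            ]
        if self.kind == "random_forest":
            return [{"n_estimators": t} for t in sorted(self.grid["n_estimators"])]
        return [{}]


@dataclass
class TrainedModel:
    """A fitted classifier bound to the column names it was trained on."""

    spec: ModelSpec
    chosen: dict
    estimator: object
    columns: tuple[str, ...]
    cv_scores: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format_version": 1, "spec": self.spec, "chosen": self.chosen,
             "estimator": self.estimator, "columns": self.columns,
             "cv_scores": self.cv_scores},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        return cls(
            spec=payload["spec"], chosen=payload["chosen"],
            estimator=payload["estimator"], columns=payload["columns"],
            cv_scores=payload.get("cv_scores", {}),
        )


# ---------------------------------------------------------------------------
# balancing / splitting

def undersample_balance(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Randomly undersample the majority class to an exact 1:1 ratio.

    Every minority-class sample is retained; majority samples are drawn
    without replacement. Retained rows keep their original relative order.
    """
    y = matrix.y()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undersampling requires both classes present")
    minority = 1 if n_pos <= n_neg else 0
    minority_idx = np.flatnonzero(y == minority)
    majority_idx = np.flatnonzero(y != minority)
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(majority_idx, size=len(minority_idx), replace=False)
    keep = np.sort(np.concatenate([minority_idx, keep_major]))
    return matrix.subset_rows(keep)


def stratified_split_indices(
    labels: Sequence, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split: round(fraction * n_class) samples go to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = list(labels)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in sorted(set(labels), key=str):
        cls_idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
        if len(cls_idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot split")
        perm = rng.permutation(cls_idx)
        n_train = int(round(fraction * len(cls_idx)))
        n_train = min(max(n_train, 1), len(cls_idx) - 1)  # both sides nonempty
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
    )


def train_test_split(
    samples: Sequence, fraction: float = 0.8, seed: int = 0, labels: Sequence | None = None
) -> tuple[list, list]:
    """Stratified split of any labeled collection (items expose ``.label``)."""
    if labels is None:
        labels = [s.label for s in samples]
    train_idx, test_idx = stratified_split_indices(labels, fraction, seed)
    items = list(samples)
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


def kfold_indices(n_samples: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, exhaustive validation folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# classifiers

def _build_estimator(kind: str, params: dict, seed: int):
    # No z-scaling: every encoder emits features on a common bounded scale
    # (compositions in [0,1], one-hots, profile scores), and standardizing
    # inflates near-constant rare-pair dimensions into pure noise axes.
    if kind == "svm_rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], random_state=seed, n_jobs=1
        )
    if kind == "logistic_regression":
        return SGDClassifier(
            loss="log_loss", tol=1e-4, max_iter=1000, random_state=seed
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _score_estimator(estimator, X: np.ndarray) -> np.ndarray:
    """Per-sample scores in [0, 1].

    SVM margins are squashed through a logistic sigmoid (monotone, so AUC is
    unchanged and cutoff 0.5 corresponds to the margin sign); RF and SGD-LR
    expose class probabilities directly.
    """
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    margins = estimator.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margins))


def grid_search_train(matrix: FeatureMatrix, spec: ModelSpec, k: int = 5) -> TrainedModel:
    """Exhaustive grid search by k-fold CV, then refit on the full matrix.

    The objective is the mean validation AUC (or accuracy when configured);
    ties break toward the first grid point in documented iteration order.
    """
    X, y = matrix.values, matrix.y()
    folds = kfold_indices(matrix.n_samples, k, spec.seed)
    all_idx = np.arange(matrix.n_samples)
    best_score, best_point = -np.inf, None
    cv_scores: dict[str, float] = {}
    for point in spec.grid_points():
        fold_scores = []
        for val_idx in folds:
            fit_idx = np.setdiff1d(all_idx, val_idx)
            if len(np.unique(y[fit_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
                raise ValueError(
                    "a CV fold contains a single class; use more data or smaller k"
                )
            est = _build_estimator(spec.kind, point, spec.seed)
            est.fit(X[fit_idx], y[fit_idx])
            scores = _score_estimator(est, X[val_idx])
            if spec.objective == "auc":
                _, area = roc_auc(scores, y[val_idx])
                fold_scores.append(area)
            else:
                counts = confusion_at_cutoff(scores, y[val_idx], spec.cutoff)
                fold_scores.append(compute_metrics(counts)["Acc"])
        mean_score = float(np.mean(fold_scores))
        cv_scores[repr(point)] = mean_score
        if mean_score > best_score:  # strict: first point wins ties
            best_score, best_point = mean_score, point
    assert best_point is not None
    final = _build_estimator(spec.kind, best_point, spec.seed)
    final.fit(X, y)
    return TrainedModel(
        spec=spec, chosen=best_point, estimator=final,
        columns=matrix.names, cv_scores=cv_scores,
    )


def predict_scores(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Scores in [0, 1] for each row; columns must match the training columns."""
    if matrix.names != model.columns:
        missing = sorted(set(model.columns) - set(matrix.names))
        extra = sorted(set(matrix.names) - set(model.columns))
        raise ValueError(
            f"feature columns do not match training columns "
            f"(missing: {missing[:5]}, extra: {extra[:5]})"
        )
    return _score_estimator(model.estimator, matrix.values)


def predict_labels(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Hard 0/1 labels at the model's cutoff (score >= cutoff is positive)."""
    return (predict_scores(model, matrix) >= model.spec.cutoff).astype(int)
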