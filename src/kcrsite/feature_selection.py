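"""Chi-square and information-gain filtering of feature dimensions.

Both selectors are *fit on the training matrix only*; the resulting
:class:`SelectionResult` is a frozen mask + scores that can be applied to any
matrix with the same columns without recomputation, so no test information can
leak into the selection.

Chi-square uses the class-wise value-sum construction for nonnegative
features: for each dimension the "observed" counts are the per-class sums of
the feature, the "expected" counts are the class priors times the feature's
total sum, and chi2 = sum (O - E)^2 / E with (classes - 1) degrees of freedom.
Dimensions whose upper-tail p-value exceeds alpha are removed. A dimension
that is identically zero has chi2 = 0, p = 1 and is removed.

Information gain discretizes each dimension (default: 2 equal-frequency bins
split at the training median) and computes H(class) - H(class | bin) in bits;
dimensions with zero gain are removed, or the top-k by gain are kept when
configured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .sequence_encoders import FeatureMatrix


@dataclass(frozen=True)
class SelectionResult:
    """Per-dimension scores and the keep mask produced by a selector."""

    names: tuple[str, ...]
    scores: np.ndarray
    kept: np.ndarray
    method: str
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        kept = np.asarray(self.kept, dtype=bool)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "kept", kept)
        if self.p_values is not None:
            object.__setattr__(self, "p_values", np.asarray(self.p_values, dtype=float))
        if not (len(self.names) == scores.shape[0] == kept.shape[0]):
            raise ValueError("names, scores and mask must have equal length")
        if not np.all(np.isfinite(scores)) or np.any(scores < 0):
            raise ValueError("scores must be finite and >= 0")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def ranking(self) -> np.ndarray:
        """Dimension indices in descending score order (stable)."""
        return np.argsort(-self.scores, kind="stable")

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        """Project a matrix onto the kept dimensions. Never recomputes scores."""
        if matrix.names != self.names:
            raise ValueError("matrix columns do not match the fitted selection")
        return matrix.select_columns(self.kept)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "names": list(self.names),
            "scores": [float(s) for s in self.scores],
            "kept": [bool(k) for k in self.kept],
            "p_values": None
            if self.p_values is None
            else [float(p) for p in self.p_values],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            names=tuple(payload["names"]),
            scores=np.array(payload["scores"]),
            kept=np.array(payload["kept"], dtype=bool),
            method=payload["method"],
            p_values=None
            if payload["p_values"] is None
            else np.array(payload["p_values"]),
        )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection requires both classes present")


def chi_square_select(matrix: FeatureMatrix, alpha: float = 0.05) -> SelectionResult:
    """Chi-square filter: keep dimensions with upper-tail p-value <= alpha."""
    X = matrix.values
    if np.any(X < 0):
        raise ValueError("chi-square selection requires nonnegative feature values")
    y = matrix.y()
    _check_two_classes(y)
    classes = np.unique(y)
    n = len(y)
    priors = np.array([(y == c).mean() for c in classes])
    observed = np.vstack([X[y == c].sum(axis=0) for c in classes])
    totals = X.sum(axis=0)
    expected = np.outer(priors, totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = terms.sum(axis=0)
    p = stats.chi2.sf(chi2, df=len(classes) - 1)
    p = np.where(totals > 0, p, 1.0)  # all-zero dimension carries no evidence
    chi2 = np.where(totals > 0, chi2, 0.0)
    return SelectionResult(
        names=matrix.names,
        scores=chi2,
        kept=p <= alpha,
        method="chi2",
        p_values=p,
    )


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; a constant dimension collapses to one bin."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right")


def information_gain(x_binned: np.ndarray, y: np.ndarray) -> float:
    """H(y) - H(y | x) in bits, by direct counting of joint frequencies."""
    classes = np.unique(y)
    n = len(y)
    h_y = _entropy_bits(np.array([(y == c).sum() for c in classes]))
    h_cond = 0.0
    for b in np.unique(x_binned):
        in_bin = x_binned == b
        weight = in_bin.sum() / n
        h_cond += weight * _entropy_bits(
            np.array([(y[in_bin] == c).sum() for c in classes])
        )
    return max(0.0, h_y - h_cond)


def information_gain_select(
    matrix: FeatureMatrix, bins: int = 2, top_k: int | None = None
) -> SelectionResult:
    """Information-gain filter: keep dimensions with gain > 0, or the top-k by gain."""
    y = matrix.y()
    _check_two_classes(y)
    gains = np.array(
        [information_gain(_discretize(matrix.values[:, d], bins), y)
         for d in range(matrix.n_features)]
    )
    if top_k is not None:
        if top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {top_k}")
        kept = np.zeros(matrix.n_features, dtype=bool)
        kept[np.argsort(-gains, kind="stable")[:top_k]] = True
    else:
        kept = gains > 0
    return SelectionResult(names=matrix.names, scores=gains, kept=kept, method="ig")
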