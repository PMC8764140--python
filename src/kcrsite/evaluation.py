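"""Confusion-matrix metrics, ROC curve and AUC for site-prediction reports.

The seven report metrics follow the study protocol's printed formulas,
including the algebraically equivalent complement forms of precision and F1:

    Sn  = TP / (TP + FN)            (= Recall)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
    Precision = 1 - FP / (TP + FP)
    F1        = 1 - (FP + FN) / (2*TP + FP + FN)

Any metric whose denominator is zero is reported as 0 and named in the
report's ``undefined`` flag list, keeping reports total and machine-readable.
A score equal to the cutoff counts as a positive prediction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_auc_score, roc_curve

from .io_formats import NEGATIVE, POSITIVE


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("confusion counts must cover at least one sample")


@dataclass(frozen=True)
class EvalReport:
    """Seven threshold metrics plus ROC/AUC and the underlying counts."""

    counts: ConfusionCounts
    Sn: float
    Sp: float
    Acc: float
    MCC: float
    Recall: float
    Precision: float
    F1: float
    AUC: float
    roc: tuple[tuple[float, float], ...]  # (FPR, TPR) points
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "counts": {
                "TP": self.counts.TP, "FP": self.counts.FP,
                "TN": self.counts.TN, "FN": self.counts.FN,
            },
            "Sn": self.Sn, "Sp": self.Sp, "Acc": self.Acc, "MCC": self.MCC,
            "Recall": self.Recall, "Precision": self.Precision, "F1": self.F1,
            "AUC": self.AUC,
            "roc": [[float(f), float(t)] for f, t in self.roc],
            "undefined": list(self.undefined),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric,value\n")
            for name in ("Sn", "Sp", "Acc", "MCC", "Recall", "Precision", "F1", "AUC"):
                fh.write(f"{name},{getattr(self, name)!r}\n")
            for name in ("TP", "FP", "TN", "FN"):
                fh.write(f"{name},{getattr(self.counts, name)}\n")


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if lab in (POSITIVE, 1, True, "1"):
            out.append(1)
        elif lab in (NEGATIVE, 0, False, "0"):
            out.append(0)
        else:
            raise ValueError(f"unrecognized class label {lab!r}")
    return np.array(out)


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence, cutoff: float = 0.5
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with score >= cutoff predicted positive."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels must have equal length")
    if scores.shape[0] == 0:
        raise ValueError("cannot tally an empty prediction set")
    pred = scores >= cutoff
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> dict:
    """The seven metrics from confusion counts, plus the undefined-flag list."""
    TP, FP, TN, FN = counts.TP, counts.FP, counts.TN, counts.FN
    undefined: list[str] = []
    sn = _safe_div(TP, TP + FN, "Sn", undefined)
    sp = _safe_div(TN, TN + FP, "Sp", undefined)
    acc = _safe_div(TP + TN, TP + FP + TN + FN, "Acc", undefined)
    mcc_den = math.sqrt(
        float(TP + FN) * float(TN + FP) * float(TP + FP) * float(TN + FN)
    )
    if mcc_den == 0:
        undefined.append("MCC")
        mcc = 0.0
    else:
        mcc = (TP * TN - FN * FP) / mcc_den
    if TP + FP == 0:
        undefined.append("Precision")
        precision = 0.0
    else:
        precision = 1.0 - FP / (TP + FP)
    if 2 * TP + FP + FN == 0:
        undefined.append("F1")
        f1 = 0.0
    else:
        f1 = 1.0 - (FP + FN) / (2 * TP + FP + FN)
    return {
        "Sn": sn, "Sp": sp, "Acc": acc, "MCC": mcc,
        "Recall": sn, "Precision": precision, "F1": f1,
        "undefined": tuple(undefined),
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (threshold sweep, descending) and the tie-aware AUC.

    The AUC equals the Mann-Whitney statistic: the probability a random
    positive outscores a random negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    area = float(roc_auc_score(y, scores))
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)], area


def evaluate_predictions(
    scores: Sequence[float], labels: Sequence, cutoff: float = 0.5
) -> EvalReport:
    """Full report: cutoff confusion, the seven metrics, ROC points and AUC."""
    counts = confusion_at_cutoff(scores, labels, cutoff)
    metrics = compute_metrics(counts)
    roc_points, area = roc_auc(scores, labels)
    return EvalReport(
        counts=counts,
        Sn=metrics["Sn"], Sp=metrics["Sp"], Acc=metrics["Acc"], MCC=metrics["MCC"],
        Recall=metrics["Recall"], Precision=metrics["Precision"], F1=metrics["F1"],
        AUC=area,
        roc=tuple(roc_points),
        undefined=metrics["undefined"],
    )


def plot_roc(report: EvalReport, path: str | Path) -> None:
    """Convenience hook: save the report's ROC curve as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [p[0] for p in report.roc]
    tpr = [p[1] for p in report.roc]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {report.AUC:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
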