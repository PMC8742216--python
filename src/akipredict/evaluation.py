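"""Discrimination metrics, bootstrap CIs, and the alert-threshold sweep.

AUROC is the Mann-Whitney probability that a random case outranks a
random control (ties count one half).  The threshold sweep turns scores
into alert counts: a sample is an alert when its predicted probability
is >= the threshold; precision, recall and F1 are reported per
threshold together with the confusion matrix, and the operating point
is chosen by the highest F1 (lowest threshold on ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def precision(self) -> float:
        npos = self.n_predicted_positive
        return self.tp / npos if npos else 0.0

    @property
    def recall(self) -> float:
        actual = self.tp + self.fn
        return self.tp / actual if actual else 0.0


@dataclass(frozen=True)
class ThresholdRow:
    threshold: float
    precision: float
    recall: float
    f1: float
    n_predicted_positive: int
    n_true_positive: int
    precision_defined: bool = True


@dataclass
class EvalReport:
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    rows: list[ThresholdRow]
    matrices: dict[float, ConfusionMatrix]
    best_f1_threshold: float
    n_samples: int = 0
    n_positive: int = 0
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matrices"] = {str(k): asdict(v) for k, v in self.matrices.items()}
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            auroc=d["auroc"], auroc_ci=tuple(d["auroc_ci"]), auprc=d["auprc"],
            rows=[ThresholdRow(**r) for r in d["rows"]],
            matrices={float(k): ConfusionMatrix(**v)
                      for k, v in d["matrices"].items()},
            best_f1_threshold=d["best_f1_threshold"],
            n_samples=d.get("n_samples", 0), n_positive=d.get("n_positive", 0),
            roc_points=[tuple(p) for p in d.get("roc_points", [])],
        )


def _check_binary(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC (rank-based, ties counted one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_binary(labels)
    return float(roc_auc_score(labels, scores))


def auroc_ci(scores: Sequence[float], labels: Sequence[int],
             n_boot: int = 2000, seed: int = 0,
             alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUROC, deterministic given seed.

    Resamples whole samples with replacement; degenerate single-class
    resamples are redrawn (their count is capped to avoid livelock on
    tiny extreme-prevalence inputs).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_binary(labels)
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 samples for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if 0 < yb.sum() < n:
                break
            redrawn += 1
        stats[b] = roc_auc_score(yb, scores[idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2 * precision * recall / (precision + recall); 0 at (0, 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float) -> ConfusionMatrix:
    """Counts with the alert rule: predicted positive iff score >= threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def row_from_matrix(threshold: float, cm: ConfusionMatrix) -> ThresholdRow:
    """Precision/recall/F1 arithmetic from raw alert counts."""
    defined = cm.n_predicted_positive > 0
    p, r = cm.precision, cm.recall
    return ThresholdRow(
        threshold=threshold, precision=p, recall=r, f1=f1_score(p, r),
        n_predicted_positive=cm.n_predicted_positive, n_true_positive=cm.tp,
        precision_defined=defined,
    )


def threshold_sweep(
    scores: Sequence[float], labels: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[list[ThresholdRow], float]:
    """One row per threshold plus argmax-F1 threshold (lowest on ties)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_binary(labels)
    rows = [row_from_matrix(t, confusion_at_threshold(scores, labels, t))
            for t in thresholds]
    best = max(rows, key=lambda r: (r.f1, -r.threshold))
    return rows, best.threshold


def evaluate(scores: Sequence[float], labels: Sequence[int],
             thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
             n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Full report: AUROC + CI, AUPRC, sweep rows, confusion matrices."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    rows, best = threshold_sweep(scores, labels, thresholds)
    fpr, tpr, _ = roc_curve(labels, scores)
    step = max(1, len(fpr) // 200)  # thin the curve for serialization
    return EvalReport(
        auroc=auroc(scores, labels),
        auroc_ci=auroc_ci(scores, labels, n_boot=n_boot, seed=seed),
        auprc=float(average_precision_score(labels, scores)),
        rows=rows,
        matrices={t: confusion_at_threshold(scores, labels, t)
                  for t in thresholds},
        best_f1_threshold=best,
        n_samples=len(labels), n_positive=int(labels.sum()),
        roc_points=[(float(f), float(t))
                    for f, t in zip(fpr[::step], tpr[::step])],
    )


def sweep_table(rows: Sequence[ThresholdRow]):
    """Threshold table as a DataFrame (threshold_table.csv schema)."""
    import pandas as pd
    return pd.DataFrame([asdict(r) for r in rows])
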