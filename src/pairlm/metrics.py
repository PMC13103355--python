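"""Evaluation metrics and machine-readable reports.

Thin, validated wrappers over scikit-learn/scipy: AUPRC uses the
step-interpolated precision-recall convention (average precision), AUROC
the Mann-Whitney formulation with tie correction, Spearman the Pearson
correlation of average ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve."""
    scores, labels = _check_binary(scores, labels)
    return float(average_precision_score(labels, scores))


def auroc(scores, labels) -> float:
    scores, labels = _check_binary(scores, labels)
    return float(roc_auc_score(labels, scores))


def correlation(pred, truth, kind: str = "pearson") -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(pred) == 0 or np.std(truth) == 0:
        raise ValueError("zero variance input")
    if kind == "pearson":
        return float(stats.pearsonr(pred, truth).statistic)
    if kind == "spearman":
        return float(stats.spearmanr(pred, truth).statistic)
    raise ValueError(f"unknown correlation kind {kind!r}")


def classification_report(probs, labels, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a probability threshold; F1 is defined as
    0 when precision + recall is 0."""
    probs, labels = _check_binary(probs, labels)
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(labels)
    return {
        "precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


@dataclass
class MetricReport:
    """Per-task metric map with provenance, serialized as JSON lines."""

    task: str
    metrics: dict
    seed: Optional[int] = None
    config_hash: Optional[str] = None
    manifest: dict = field(default_factory=dict)

    def validate(self):
        bounded = {"auroc", "auprc", "precision", "recall", "accuracy", "f1"}
        for name, value in self.metrics.items():
            if name in bounded and not (0.0 <= value <= 1.0):
                raise ValueError(f"metric {name}={value} outside [0, 1]")
            if name in ("pcc", "srcc") and not (-1.0 <= value <= 1.0):
                raise ValueError(f"metric {name}={value} outside [-1, 1]")
        return self

    def to_json(self) -> str:
        return json.dumps({
            "task": self.task, "metrics": self.metrics, "seed": self.seed,
            "config_hash": self.config_hash, "manifest": self.manifest,
        }, sort_keys=True)


def write_reports(reports, path):
    with open(path, "a") as fh:
        for r in reports:
            fh.write(r.validate().to_json() + "\n")
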