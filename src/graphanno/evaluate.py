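"""Annotation and embedding metrics: ACC, NMI, F1, weighted F1, silhouette."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "MetricReport",
    "accuracy",
    "f1_scores",
    "nmi",
    "silhouette",
    "edge_auc",
    "metric_report",
]


@dataclass
class MetricReport:
    acc: float
    nmi: float
    f1_per_label: dict
    macro_f1: float
    weighted_f1: float
    asw: float | None
    asw_per_label: dict | None
    n_evaluated: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        return cls(**json.loads(text))


def _check_aligned(truth, pred) -> tuple[list, list]:
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    if not truth:
        raise ValueError("empty label vectors")
    return truth, pred


def accuracy(truth, pred) -> float:
    truth, pred = _check_aligned(truth, pred)
    return float(np.mean([t == p for t, p in zip(truth, pred)]))


def f1_scores(truth, pred) -> tuple[dict, float, float]:
    """Per-label, macro and support-weighted F1.

    Labels present in the truth but never predicted get F1 = 0 with a
    warning (their recall is zero anyway; the warning flags the collapse).
    """
    truth, pred = _check_aligned(truth, pred)
    labels = sorted(set(truth))
    missing = set(truth) - set(pred)
    if missing:
        warnings.warn(f"labels never predicted (F1=0): {sorted(missing)}")
    per = skm.f1_score(truth, pred, labels=labels, average=None, zero_division=0)
    per_label = {lab: float(v) for lab, v in zip(labels, per)}
    macro = float(np.mean(per))
    weighted = float(
        skm.f1_score(truth, pred, labels=labels, average="weighted", zero_division=0)
    )
    return per_label, macro, weighted


def nmi(truth, pred, average_method: str = "arithmetic") -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    A degenerate single-class partition on either side is defined as 0.
    """
    truth, pred = _check_aligned(truth, pred)
    if len(set(truth)) < 2 or len(set(pred)) < 2:
        warnings.warn("single-class partition; NMI defined as 0")
        return 0.0
    return float(
        skm.normalized_mutual_info_score(truth, pred, average_method=average_method)
    )


def silhouette(coords: np.ndarray, labels) -> tuple[np.ndarray, dict, float]:
    """Euclidean silhouette: per-cell widths, per-type means and grand mean.

    Singleton types get silhouette 0 for their cells (with a warning).
    """
    labels = np.asarray(list(labels))
    coords = np.asarray(coords, dtype=float)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 types")
    if np.any(counts == 1):
        warnings.warn(f"singleton types get silhouette 0: {uniq[counts == 1].tolist()}")
    per_cell = skm.silhouette_samples(coords, labels)
    per_type = {str(u): float(per_cell[labels == u].mean()) for u in uniq}
    return per_cell, per_type, float(per_cell.mean())


def edge_auc(G_hat: np.ndarray, positives: np.ndarray, negatives: np.ndarray) -> float:
    """ROC AUC of decoded probabilities on held-out edges vs sampled non-edges."""
    scores = np.concatenate([
        G_hat[positives[:, 0], positives[:, 1]],
        G_hat[negatives[:, 0], negatives[:, 1]],
    ])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    return float(skm.roc_auc_score(y, scores))


def metric_report(
    truth, pred, embedding: np.ndarray | None = None
) -> MetricReport:
    truth, pred = _check_aligned(truth, pred)
    per_label, macro, weighted = f1_scores(truth, pred)
    asw = asw_per = None
    if embedding is not None:
        _, asw_per, asw = silhouette(embedding, truth)
    return MetricReport(
        acc=accuracy(truth, pred),
        nmi=nmi(truth, pred),
        f1_per_label=per_label,
        macro_f1=macro,
        weighted_f1=weighted,
        asw=asw,
        asw_per_label=asw_per,
        n_evaluated=len(truth),
    )
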