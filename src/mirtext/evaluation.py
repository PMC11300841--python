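"""Evaluation metrics for NER and relation classification.

NER is scored at entity level with exact-span matching: a predicted mention
counts as a true positive only when (start, end, class) all agree with a gold
mention of the same sentence. Micro scores pool tp/fp/fn over classes. The
degenerate 0/0 precision or recall is reported as 0 (supports are always
reported alongside, so the convention is visible).

Relation classification uses threshold-free ranking metrics: AUROC (equal to
the Mann-Whitney pairwise concordance probability, ties counted 1/2) and
AUPR as non-interpolated average precision. Both delegate to scikit-learn.

Cross-validation is stratified k-fold with per-fold metric values and
mean +/- sd aggregation, deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .corpus_io import EntityMention


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return cls(precision, recall, f1, tp, fp, fn)


def _mention_keys(sentences: Sequence[Sequence[EntityMention]]) -> set[tuple]:
    return {
        (s_i, m.start, m.end, m.entity_class.value)
        for s_i, mentions in enumerate(sentences)
        for m in mentions
    }


def ner_prf(gold: Sequence[Sequence[EntityMention]],
            predicted: Sequence[Sequence[EntityMention]],
            matching: str = "exact") -> dict[str, PRF]:
    """Entity-level precision/recall/F1 per class plus micro average.

    ``gold`` and ``predicted`` are parallel per-sentence mention lists.
    ``matching="overlap"`` relaxes true positives to any same-class span
    overlap; exact is the default and the reported standard.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must cover the same sentences")
    gold_keys = _mention_keys(gold)
    pred_keys = _mention_keys(predicted)
    classes = sorted({k[3] for k in gold_keys | pred_keys})
    report: dict[str, PRF] = {}
    total_tp = total_fp = total_fn = 0
    for cls in classes:
        g = {k for k in gold_keys if k[3] == cls}
        p = {k for k in pred_keys if k[3] == cls}
        if matching == "exact":
            tp = len(g & p)
            fp, fn = len(p) - tp, len(g) - tp
        elif matching == "overlap":
            tp = sum(
                1 for (s_i, ps, pe, _c) in p
                if any(gs < pe and ge > ps
                       for (g_i, gs, ge, _gc) in g if g_i == s_i)
            )
            fp = len(p) - tp
            fn = sum(
                1 for (s_i, gs, ge, _c) in g
                if not any(ps < ge and pe > gs
                           for (p_i, ps, pe, _pc) in p if p_i == s_i)
            )
        else:
            raise ValueError(f"unknown matching mode {matching!r}")
        report[cls] = PRF.from_counts(tp, fp, fn)
        total_tp += tp
        total_fp += fp
        total_fn += fn
    report["micro"] = PRF.from_counts(total_tp, total_fp, total_fn)
    return report


def confusion_matrix(labels: Sequence[int],
                     predicted: Sequence[int]) -> dict[str, int]:
    """Binary confusion counts; the four cells sum to ``len(labels)``."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions differ in length")
    return {
        "tp": int(np.sum((labels == 1) & (predicted == 1))),
        "fp": int(np.sum((labels == 0) & (predicted == 1))),
        "fn": int(np.sum((labels == 1) & (predicted == 0))),
        "tn": int(np.sum((labels == 0) & (predicted == 0))),
    }


def _check_scores(labels: np.ndarray, scores: np.ndarray) -> None:
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) with ties at 1/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_scores(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("auroc requires at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_scores(labels, scores)
    if labels.sum() == 0:
        raise ValueError("aupr requires at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass
class CVReport:
    metric_name: str
    per_fold: list[float]
    k: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold, ddof=0))


def cross_validate(labels: Sequence[int], k: int, seed: int,
                   trainer: Callable[[np.ndarray, np.ndarray], Sequence[float]],
                   metric: Callable[[np.ndarray, np.ndarray], float],
                   metric_name: str = "auroc") -> CVReport:
    """Stratified k-fold CV; mean and sd over per-fold metric values.

    ``trainer(train_idx, val_idx)`` fits on the training fold and returns
    scores for the validation fold; ``metric(val_labels, val_scores)``
    evaluates them. Folds are stratified on ``labels``, disjoint, covering,
    and deterministic for the seed.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _values, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"rarest label has {counts.min()} instances, fewer than k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[float] = []
    for train_idx, val_idx in splitter.split(np.zeros(len(labels)), labels):
        scores = np.asarray(trainer(train_idx, val_idx), dtype=float)
        per_fold.append(float(metric(labels[val_idx], scores)))
    return CVReport(metric_name=metric_name, per_fold=per_fold, k=k, seed=seed)
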