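"""Metrics, cross-validation driver, and the random-prediction baseline.

Five criteria are reported per scored test set: accuracy, AUPR, AUROC,
F1 and the Matthews correlation coefficient (MCC), the most informative of
the five on imbalanced bind/non-bind data.  Confusion-matrix metrics use a
0.5 threshold on the positive-class probability; AUPR is step-integrated
(average precision) and AUROC trapezoidal.  Degenerate confusion matrices
(single-class predictions or labels) define MCC as 0; single-class labels
leave AUPR/AUROC undefined.

The random baseline draws labels at a chosen prevalence and scores
uniformly: its expected AUPR equals the prevalence and its expected MCC is
0, the floor any real model must beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn import metrics as skm

__all__ = ["EvalReport", "compute_metrics", "random_baseline", "cross_validate", "aggregate_reports"]


@dataclass
class EvalReport:
    accuracy: float
    auroc: float
    aupr: float
    f1: float
    mcc: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None  # (precision, recall)
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "f1": self.f1,
            "mcc": self.mcc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    with_curves: bool = False,
) -> EvalReport:
    """Score a test set of positive-class probabilities against 0/1 labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError(f"scores/labels length mismatch: {s.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = (s >= threshold).astype(int)
    undefined: list[str] = []
    accuracy = float(np.mean(pred == y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = float(skm.f1_score(y, pred, zero_division=0))
        mcc = float(skm.matthews_corrcoef(y, pred))  # degenerate -> 0 by convention
    single_class = len(np.unique(y)) < 2
    if single_class:
        auroc = aupr = float("nan")
        undefined += ["auroc", "aupr"]
        pr = roc = None
    else:
        auroc = float(skm.roc_auc_score(y, s))
        aupr = float(skm.average_precision_score(y, s))
        precision, recall, _ = skm.precision_recall_curve(y, s)
        fpr, tpr, _ = skm.roc_curve(y, s)
        pr, roc = (precision, recall), (fpr, tpr)
    return EvalReport(
        accuracy=accuracy,
        auroc=auroc,
        aupr=aupr,
        f1=f1,
        mcc=mcc,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
        threshold=threshold,
        pr_curve=pr if with_curves else None,
        roc_curve=roc if with_curves else None,
        undefined=undefined,
    )


def random_baseline(n: int, prevalence: float, seed: int = 0) -> EvalReport:
    """Uniform-random scorer on Bernoulli(prevalence) labels.

    Expected AUPR ~ prevalence, expected MCC ~ 0.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prevalence).astype(int)
    scores = rng.random(n)
    return compute_metrics(scores, labels)


def aggregate_reports(reports: Sequence[EvalReport]) -> dict[str, tuple[float, float]]:
    """Mean +/- sd per metric; NaN (undefined) fold values are excluded."""
    out: dict[str, tuple[float, float]] = {}
    for name in ("accuracy", "auroc", "aupr", "f1", "mcc"):
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        values = values[np.isfinite(values)]
        if len(values):
            out[name] = (float(values.mean()), float(values.std(ddof=0)))
        else:
            out[name] = (float("nan"), float("nan"))
    return out


def cross_validate(
    x_compound: np.ndarray,
    x_target: np.ndarray,
    y: np.ndarray,
    fold_of: np.ndarray,
    model_factory: Callable[[int], object],
    train_fn: Callable,
    train_config=None,
) -> tuple[list[EvalReport], dict[str, tuple[float, float]], list[int]]:
    """k-fold cross-validation: train on each fold's complement, test on it.

    ``model_factory(fold)`` builds a fresh model per fold (seeded by fold id
    on top of the config seed for reproducibility); ``train_fn(model, xc,
    xt, y, config)`` runs training.  Folds whose test labels are
    single-class are flagged and excluded from AUPR/AUROC aggregation
    (their NaN entries are skipped by :func:`aggregate_reports`).
    """
    fold_of = np.asarray(fold_of)
    y = np.asarray(y, dtype=int)
    folds = sorted(np.unique(fold_of))
    if not np.isin(np.arange(len(y)), np.arange(len(y))[np.isin(fold_of, folds)]).all():
        raise ValueError("fold assignment does not cover all records")
    reports: list[EvalReport] = []
    flagged: list[int] = []
    for fold in folds:
        test = fold_of == fold
        model = model_factory(int(fold))
        train_fn(model, x_compound[~test], x_target[~test], y[~test], train_config)
        scores = model.predict_proba(x_compound[test], x_target[test])
        report = compute_metrics(scores, y[test])
        if report.undefined:
            flagged.append(int(fold))
        reports.append(report)
    return reports, aggregate_reports(reports), flagged
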