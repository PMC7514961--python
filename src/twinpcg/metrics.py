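"""Confusion-matrix bookkeeping, the five evaluation measures, and CV.

Throughout, *abnormal* is the positive class: TP counts abnormal records
identified as abnormal, TN healthy records identified as healthy. The five
measures — accuracy, sensitivity (= recall), specificity, precision and F1 —
are reported in percent. A measure whose denominator is zero is undefined
and raises :class:`UndefinedMetricError` rather than silently returning 0,
because silent zeros corrupt grid searches.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .twsvm import TrainingSet, TwinSVM


class UndefinedMetricError(ZeroDivisionError):
    """A requested measure has a zero denominator for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self):
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class MetricReport:
    """The five measures, in percent."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred, truth) -> ConfusionCounts:
    """Tally TP/FN/TN/FP from +1/-1 label sequences (+1 = abnormal)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty 1-D")
    for arr, name in ((pred, "pred"), (truth, "truth")):
        if not set(np.unique(arr)) <= {-1, 1}:
            raise ValueError(f"{name} labels must be in {{+1, -1}}")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        FN=int(np.sum((pred == -1) & (truth == 1))),
        TN=int(np.sum((pred == -1) & (truth == -1))),
        FP=int(np.sum((pred == 1) & (truth == -1))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined: zero denominator")
    return 100.0 * num / den


def accuracy(counts: ConfusionCounts) -> float:
    return _ratio(counts.TP + counts.TN, counts.total, "accuracy")


def report(counts: ConfusionCounts) -> MetricReport:
    """Evaluate the five measures; raises naming any undefined one."""
    acc = accuracy(counts)
    sens = _ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    spec = _ratio(counts.TN, counts.TN + counts.FP, "specificity")
    prec = _ratio(counts.TP, counts.TP + counts.FP, "precision")
    if sens + prec == 0:
        raise UndefinedMetricError("F1 is undefined: recall + precision is zero")
    f1 = 2.0 * sens * prec / (sens + prec)
    return MetricReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        precision=prec, f1=f1)


@dataclass(frozen=True)
class CVResult:
    best_params: dict
    best_mean_accuracy: float
    mean_accuracies: tuple[float, ...]   # one per grid point, grid order
    fold_reports: tuple[MetricReport, ...]  # at the best point
    fold_indices: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train, val)


def cross_validate(
    train: TrainingSet,
    folds: int = 10,
    hyper_grid: list[dict] | None = None,
    seed: int = 0,
    model_factory=TwinSVM,
) -> CVResult:
    """Stratified k-fold grid search maximizing mean validation accuracy.

    Ties between grid points go to the first in grid order. The fold
    assignments are returned so the selection can be audited or recomputed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = train.y
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"stratification infeasible: smallest class has "
            f"{min(n_pos, n_neg)} members < {folds} folds"
        )
    if hyper_grid is None:
        hyper_grid = [{}]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = tuple((tr, va) for tr, va in skf.split(train.X, y))

    fold_preds_per_point: list[list[np.ndarray]] = []
    means: list[float] = []
    for params in hyper_grid:
        preds = []
        fold_accs = []
        for tr, va in splits:
            model = model_factory(**params)
            model.fit(train.X[tr], y[tr])
            p = model.predict(train.X[va])
            preds.append(p)
            fold_accs.append(100.0 * np.mean(p == y[va]))
        fold_preds_per_point.append(preds)
        means.append(float(np.mean(fold_accs)))

    best = int(np.argmax(means))  # first max wins ties
    reports = tuple(
        report(confusion(p, y[va]))
        for p, (_, va) in zip(fold_preds_per_point[best], splits)
    )
    return CVResult(
        best_params=dict(hyper_grid[best]),
        best_mean_accuracy=means[best],
        mean_accuracies=tuple(means),
        fold_reports=reports,
        fold_indices=splits,
    )
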