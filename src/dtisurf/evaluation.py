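"""Confusion-matrix metrics, ROC/AUC and the k-fold CV protocol.

Metrics follow the usual binary conventions: accuracy, sensitivity
(TPR = TP/(TP+FN)), precision (PPV = TP/(TP+FP)) and the Matthews
correlation coefficient.  Cross-validation is stratified and seeded:
the dataset is shuffled into k folds (default 5), each fold once held
out while the model trains on the rest; per-fold metrics plus their
mean and standard deviation are reported, and per-fold positive-class
scores feed a ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import welm
from .dataio import PairSample, dataset_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class FoldMetrics:
    fold: int
    acc: float
    tpr: float
    ppv: float
    mcc: float
    auc: float
    counts: ConfusionCounts
    degenerate: bool = False


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and standard deviation per column."""

    per_fold: list

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(f, name) for f in self.per_fold])

    def mean(self, name: str) -> float:
        return float(self._values(name).mean())

    def std(self, name: str) -> float:
        return float(self._values(name).std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    def to_table(self) -> pd.DataFrame:
        """Per-fold table (percentages) with a trailing mean +/- sd row."""
        rows = [
            {
                "Testing set": str(f.fold),
                "Acc (%)": f"{100 * f.acc:.2f}",
                "TPR (%)": f"{100 * f.tpr:.2f}",
                "PPV (%)": f"{100 * f.ppv:.2f}",
                "MCC (%)": f"{100 * f.mcc:.2f}",
                "AUC": f"{f.auc:.4f}",
            }
            for f in self.per_fold
        ]
        rows.append(
            {
                "Testing set": "Average",
                "Acc (%)": f"{100 * self.mean('acc'):.2f} ± {100 * self.std('acc'):.2f}",
                "TPR (%)": f"{100 * self.mean('tpr'):.2f} ± {100 * self.std('tpr'):.2f}",
                "PPV (%)": f"{100 * self.mean('ppv'):.2f} ± {100 * self.std('ppv'):.2f}",
                "MCC (%)": f"{100 * self.mean('mcc'):.2f} ± {100 * self.std('mcc'):.2f}",
                "AUC": f"{self.mean('auc'):.4f} ± {self.std('auc'):.4f}",
            }
        )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """2x2 cross-tabulation of binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        TP=int((t & p).sum()),
        TN=int((~t & ~p).sum()),
        FP=int((~t & p).sum()),
        FN=int((t & ~p).sum()),
    )


def metrics(c: ConfusionCounts, legacy_tpr: bool = False):
    """(acc, tpr, ppv, mcc, degenerate_flag) from confusion counts.

    acc = (TP+TN)/total, tpr = TP/(TP+FN), ppv = TP/(TP+FP),
    mcc = (TP*TN - FP*FN)/sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    Any zero denominator yields 0 for that metric and sets the
    degenerate flag instead of raising, so CV sweeps never abort.
    ``legacy_tpr`` switches the sensitivity denominator to TP+TN, a
    non-standard variant retained for auditing older reports.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    acc = (c.TP + c.TN) / c.total
    tpr = ratio(c.TP, c.TP + c.TN) if legacy_tpr else ratio(c.TP, c.TP + c.FN)
    ppv = ratio(c.TP, c.TP + c.FP)
    denom = (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    if denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(denom))
    return acc, tpr, ppv, float(mcc), degenerate


def roc_auc(y_true, scores, positive=1):
    """ROC curve by threshold sweep and its trapezoid-rule AUC.

    The trapezoid AUC over the empirical ROC equals the Mann-Whitney
    probability that a random positive outscores a random negative
    (ties counting one half).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def kfold_cross_validate(
    dataset,
    config: welm.WELMConfig = welm.WELMConfig(),
    k: int = 5,
    seed: int = 0,
    positive=1,
):
    """Stratified k-fold CV of the (weighted) ELM on a pair dataset.

    ``dataset`` is either a list of :class:`PairSample` or an ``(X, y)``
    tuple.  Folds are a seeded stratified shuffle; each model trains on
    k-1 folds (feature scaling statistics come from those folds only,
    inside :func:`welm.fit`) and is evaluated on the held-out fold.
    Returns ``(MetricsReport, roc_points)`` where ``roc_points`` maps
    fold number to its ROC curve array.
    """
    if isinstance(dataset, tuple):
        X, y = dataset
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    else:
        X, y = dataset_arrays(dataset)
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold, roc_points = [], {}
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), start=1):
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            raise ValueError(
                f"fold {fold}: a class is absent from the training part; "
                "use stratification or change the seed"
            )
        model = welm.fit(X[train_idx], y_train, config)
        y_pred = welm.predict(model, X[test_idx])
        scores = welm.decision_scores(model, X[test_idx])
        pos_col = model.class_order.index(positive)
        c = confusion(y[test_idx], y_pred, positive=positive)
        acc, tpr, ppv, mcc, degenerate = metrics(c)
        try:
            curve, auc = roc_auc(y[test_idx], scores[:, pos_col], positive=positive)
        except ValueError:
            curve, auc = np.empty((0, 2)), float("nan")
            degenerate = True
        per_fold.append(FoldMetrics(fold, acc, tpr, ppv, mcc, auc, c, degenerate))
        roc_points[fold] = curve
    return MetricsReport(per_fold), roc_points
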