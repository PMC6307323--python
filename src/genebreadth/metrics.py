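"""k-fold cross-validation harness and confusion-table performance measures.

Predictions from all held-out folds are pooled into a single confusion table
before any measure is computed, so each evaluated model yields one
SN/SP/ACC/MCC/J record:

    SN  = TP / (TP + FN)            (sensitivity, positive = widely expressed)
    SP  = TN / (TN + FP)            (specificity)
    ACC = (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    J   = SN + SP - 1               (Youden's index)

Youden's index is the selection criterion throughout because the two classes
are heavily imbalanced (roughly 4.7 positives per negative), which makes raw
accuracy a poor guide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from . import classifiers as _clf


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (1..k) per sample, plus the seed that produced it."""

    folds: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        folds = np.asarray(self.folds, dtype=int)
        object.__setattr__(self, "folds", folds)
        if folds.ndim != 1:
            raise DomainError("folds must be a 1-D vector")
        present = np.unique(folds)
        if present.min() < 1 or present.max() > self.k:
            raise DomainError("fold indices must lie in 1..k")
        sizes = np.bincount(folds, minlength=self.k + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise DomainError("fold sizes must differ by at most 1")

    @property
    def n(self) -> int:
        return self.folds.size


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise DomainError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsRecord:
    SN: float
    SP: float
    ACC: float
    MCC: float
    J: float


def kfold_assign(n: int, k: int, seed: int,
                 strata: Sequence[int] | None = None) -> FoldAssignment:
    """Random balanced partition of ``n`` samples into ``k`` folds.

    With ``strata`` (class labels) the balance additionally holds within each
    class: indices are shuffled within class and dealt round-robin with a
    cursor that runs across classes, so overall fold sizes still differ by at
    most one.  Deterministic given the seed.
    """
    if k < 2:
        raise DomainError("k must be >= 2")
    if n < k:
        raise DomainError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.zeros(n, dtype=int)
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        if strata.shape != (n,):
            raise DomainError("strata must have length n")
        groups = [np.flatnonzero(strata == c) for c in np.unique(strata)]
    cursor = 0
    for idx in groups:
        idx = idx[rng.permutation(idx.size)]
        for i in idx:
            folds[i] = cursor % k + 1
            cursor += 1
    return FoldAssignment(folds, k, seed)


def cross_validate(X, y, spec: "_clf.ClassifierSpec",
                   folds: FoldAssignment) -> ConfusionCounts:
    """Train on each fold's complement, predict the fold, pool the counts."""
    Xa, _ = _clf._as_array(X, None)
    y = np.asarray(y)
    if Xa.shape[0] != folds.n or y.shape[0] != folds.n:
        raise DomainError("fold assignment must cover every row of X and y")
    tp = tn = fp = fn = 0
    for fold in range(1, folds.k + 1):
        test = folds.folds == fold
        train_mask = ~test
        if len(np.unique(y[train_mask])) < 2:
            raise DomainError(
                f"training complement of fold {fold} has a single class")
        clf = _clf.train(spec, Xa[train_mask], y[train_mask])
        pred = _clf.predict(clf, Xa[test])
        truth = y[test]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def compute_metrics(cc: ConfusionCounts) -> MetricsRecord:
    """SN/SP/ACC/MCC and Youden's J from a pooled confusion table."""
    if cc.TP + cc.FN == 0:
        raise DomainError("no positive samples in truth")
    if cc.TN + cc.FP == 0:
        raise DomainError("no negative samples in truth")
    sn = cc.TP / (cc.TP + cc.FN)
    sp = cc.TN / (cc.TN + cc.FP)
    acc = (cc.TP + cc.TN) / cc.total
    denom = ((cc.TP + cc.FP) * (cc.TP + cc.FN)
             * (cc.TN + cc.FP) * (cc.TN + cc.FN))
    if denom == 0:
        mcc = 0.0     # zero-denominator convention
    else:
        mcc = (cc.TP * cc.TN - cc.FP * cc.FN) / np.sqrt(float(denom))
    return MetricsRecord(SN=sn, SP=sp, ACC=acc, MCC=float(mcc),
                         J=sn + sp - 1.0)


def write_metrics_table(records: Sequence[tuple[int, MetricsRecord]],
                        path) -> None:
    """Write (n_features, SN, SP, ACC, MCC, J) rows as TSV."""
    import pandas as pd

    df = pd.DataFrame(
        [(n, r.SN, r.SP, r.ACC, r.MCC, r.J) for n, r in records],
        columns=["n_features", "SN", "SP", "ACC", "MCC", "J"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
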