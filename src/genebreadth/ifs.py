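"""Two-step incremental feature selection (IFS) over an mRMR-ranked list.

Testing every prefix of a long ranked list is too expensive, so the scan has
two stages: a coarse pass over prefix sizes step, 2*step, ... (default step
10), then an exhaustive pass over every size in a window around the coarse
Youden-index argmax (default half-width 50).  The prefix size with the
highest cross-validated Youden index over both stages — ties going to the
smaller size — defines the optimum feature set, and the classifier retrained
on all samples with that prefix is the optimum classifier.

One fold assignment (one seed) is reused for every evaluated size so the
resulting curves are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import ClassifierSpec, TrainedClassifier, train
from .enrichment import FeatureMatrix
from .errors import DomainError
from .metrics import (MetricsRecord, compute_metrics, cross_validate,
                      kfold_assign)
from .mrmr import RankedFeatureList


@dataclass(frozen=True)
class IFSRecord:
    n_features: int
    metrics: MetricsRecord

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise DomainError("n_features must be >= 1")


@dataclass(frozen=True)
class IFSResult:
    stage1: tuple[IFSRecord, ...]
    interval: tuple[int, int]
    stage2: tuple[IFSRecord, ...]
    optimum_size: int
    optimum_metrics: MetricsRecord
    optimum_classifier: TrainedClassifier

    def all_records(self) -> tuple[IFSRecord, ...]:
        return self.stage1 + self.stage2


def stage1_sizes(n_features: int, step: int = 10) -> list[int]:
    """Coarse grid: step, 2*step, ..., plus the full size if not a multiple."""
    if n_features < 1:
        raise DomainError("n_features must be >= 1")
    if step < 1:
        raise DomainError("step must be >= 1")
    sizes = list(range(step, n_features + 1, step))
    if not sizes or sizes[-1] != n_features:
        sizes.append(n_features)
    return sizes


def stage2_interval(best_size: int, width: int = 50,
                    n_features: int | None = None) -> tuple[int, int]:
    """Symmetric window [best-width, best+width], clipped to [1, n_features]."""
    if best_size < 1:
        raise DomainError("best_size must be >= 1")
    lo = max(1, best_size - width)
    hi = best_size + width
    if n_features is not None:
        hi = min(hi, n_features)
    return lo, hi


def run_ifs(X, y, ranked: RankedFeatureList, spec: ClassifierSpec,
            step: int = 10, width: int = 50, folds: int = 10,
            seed: int = 0, interval: tuple[int, int] | None = None,
            stratified: bool = True) -> IFSResult:
    """Run the two-step IFS scan and return curves plus the optimum model.

    ``interval`` overrides the automatic stage-2 window (for replication of
    hand-chosen windows).  The same stratified fold assignment is reused for
    every size; sizes shared by both stages are evaluated once.
    """
    if isinstance(X, FeatureMatrix):
        Xa = X.scores
        feature_ids = X.feature_ids
    else:
        Xa = np.asarray(X, dtype=float)
        feature_ids = ranked.feature_ids
    y = np.asarray(y)
    n_features = Xa.shape[1]
    if len(ranked) != n_features:
        raise DomainError("ranking does not cover X's features")

    order = np.asarray(ranked.order)
    fold_assign = kfold_assign(Xa.shape[0], folds, seed,
                               strata=y if stratified else None)
    cache: dict[int, MetricsRecord] = {}

    def evaluate(size: int) -> MetricsRecord:
        if size not in cache:
            cc = cross_validate(Xa[:, order[:size]], y, spec, fold_assign)
            cache[size] = compute_metrics(cc)
        return cache[size]

    s1 = [IFSRecord(s, evaluate(s)) for s in stage1_sizes(n_features, step)]
    best1 = min(s1, key=lambda r: (-r.metrics.J, r.n_features))
    if interval is None:
        interval = stage2_interval(best1.n_features, width, n_features)
    lo, hi = interval
    if not (1 <= lo <= hi <= n_features):
        raise DomainError(f"invalid stage-2 interval [{lo}, {hi}]")
    s2 = [IFSRecord(s, evaluate(s)) for s in range(lo, hi + 1)]

    every = s1 + s2
    best = min(every, key=lambda r: (-r.metrics.J, r.n_features))
    opt_cols = order[: best.n_features]
    opt_clf = train(spec, Xa[:, opt_cols], y)
    if feature_ids is not None:
        opt_clf = TrainedClassifier(
            opt_clf.spec, opt_clf.model,
            tuple(feature_ids[i] for i in opt_cols))
    return IFSResult(stage1=tuple(s1), interval=(lo, hi), stage2=tuple(s2),
                     optimum_size=best.n_features,
                     optimum_metrics=best.metrics,
                     optimum_classifier=opt_clf)
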