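"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Features are ranked greedily: the first feature maximizes relevance
``D = I(c, f)`` (mutual information with the class), and each subsequent
feature maximizes ``D - R`` where ``R`` is the mean MI between the candidate
and the already-selected features (``R = 0`` while nothing is selected).

Continuous enrichment scores are discretized into equal-frequency bins
(default 4) and MI is the plug-in estimate over the empirical contingency
table, in nats.  The MI base only rescales D and R jointly, so it cannot
change the ranking.  Ties on D - R break to the lowest original feature
index, which makes the ranking fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .enrichment import FeatureMatrix
from .io_formats import GeneLabelTable

DEFAULT_BINS = 4


@dataclass(frozen=True)
class RankedFeatureList:
    """The mRMR list: feature indices in selection order plus relevances.

    ``order[k]`` is the original index of the (k+1)-th selected feature;
    ``relevance[i]`` is I(class, feature i) for the *original* index i.
    """

    order: tuple[int, ...]
    relevance: tuple[float, ...]
    feature_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.relevance)
        if sorted(self.order) != list(range(n)):
            raise DomainError("order must be a permutation of 0..N-1")
        if self.feature_ids is not None and len(self.feature_ids) != n:
            raise DomainError("feature_ids length does not match")

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> tuple[int, ...]:
        return self.order[:k]

    def top_ids(self, k: int) -> tuple[str, ...]:
        if self.feature_ids is None:
            raise DomainError("ranking carries no feature ids")
        return tuple(self.feature_ids[i] for i in self.order[:k])

    def to_frame(self):
        import pandas as pd

        ids = self.feature_ids or tuple(str(i) for i in range(len(self)))
        return pd.DataFrame({
            "rank": np.arange(1, len(self) + 1),
            "feature_id": [ids[i] for i in self.order],
            "feature_index": list(self.order),
            "relevance": [self.relevance[i] for i in self.order],
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path) -> "RankedFeatureList":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=0)
        order = tuple(int(i) for i in df["feature_index"])
        rel = np.zeros(len(order))
        rel[list(order)] = df["relevance"].to_numpy()
        ids = [""] * len(order)
        for i, fid in zip(order, df["feature_id"].astype(str)):
            ids[i] = fid
        return cls(order, tuple(rel), tuple(ids))


def discretize(values: Sequence[float], n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency binning into integer labels 0..n_bins-1.

    Bin edges are the interior quantiles of the data, so each bin holds an
    (almost) equal share of the samples.  A constant vector collapses to a
    single bin; if ties leave fewer distinct edges than requested the
    effective bin count shrinks with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise DomainError("values must be finite")
    if n_bins < 2:
        raise DomainError("n_bins must be >= 2")
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(edges)
    labels = np.searchsorted(edges, values, side="left").astype(np.int64)
    if len(np.unique(values)) < n_bins:
        warnings.warn(
            f"only {len(np.unique(values))} distinct values for {n_bins} bins")
    return labels


def mutual_information(a: Sequence[int], b: Sequence[int]) -> float:
    """Plug-in mutual information (nats) between two label vectors.

    Computes ``sum p(a,b) ln[p(a,b) / (p(a) p(b))]`` over occupied cells of
    the empirical contingency table; nonnegative and symmetric.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("inputs must be 1-D vectors of equal length")
    if a.size < 2:
        raise DomainError("need at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    return _mi_from_codes(ai, bi, ai.max() + 1, bi.max() + 1)


def _mi_from_codes(ai: np.ndarray, bi: np.ndarray, ka: int, kb: int) -> float:
    """MI for pre-coded vectors (codes 0..ka-1 / 0..kb-1); the hot path."""
    n = ai.size
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).astype(float)
    joint = joint.reshape(ka, kb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_rank(X: FeatureMatrix | np.ndarray,
              y: GeneLabelTable | Sequence[int],
              n_bins: int = DEFAULT_BINS,
              max_rank_depth: int | None = None) -> RankedFeatureList:
    """Produce the mRMR feature list for a feature matrix and binary target.

    ``X`` may be a :class:`FeatureMatrix` (rows aligned to its gene order,
    with ``y`` a :class:`GeneLabelTable` covering those genes) or a plain
    array with an integer label vector.  With ``max_rank_depth = K`` only the
    first K positions are ranked greedily; the remainder is appended in
    descending-relevance order (ties to the lowest index), which preserves
    the permutation contract while skipping redundancy work no downstream
    prefix will use.
    """
    feature_ids: tuple[str, ...] | None = None
    if isinstance(X, FeatureMatrix):
        feature_ids = X.feature_ids
        if isinstance(y, GeneLabelTable):
            y = y.y(gene_order=X.gene_ids)
        X = X.scores
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DomainError(
            f"X rows ({X.shape[0] if X.ndim == 2 else '?'}) must align with "
            f"y ({y.shape[0]})")
    n_samples, n_features = X.shape
    if n_features < 1:
        raise DomainError("need at least one feature")

    _, yc = np.unique(y, return_inverse=True)
    ky = int(yc.max()) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        disc = np.empty((n_features, n_samples), dtype=np.int64)
        kf = np.empty(n_features, dtype=np.int64)
        for j in range(n_features):
            lab = discretize(X[:, j], n_bins)
            disc[j] = lab
            kf[j] = lab.max() + 1

    relevance = np.array([_mi_from_codes(disc[j], yc, kf[j], ky)
                          for j in range(n_features)])

    depth = n_features if max_rank_depth is None else min(max_rank_depth,
                                                          n_features)
    selected: list[int] = []
    red_sum = np.zeros(n_features)
    remaining = np.ones(n_features, dtype=bool)
    score = relevance.copy()
    for _ in range(depth):
        masked = np.where(remaining, score, -np.inf)
        best = int(np.argmax(masked))     # argmax ties -> lowest index
        selected.append(best)
        remaining[best] = False
        if remaining.any():
            idx = np.flatnonzero(remaining)
            for j in idx:
                red_sum[j] += _mi_from_codes(disc[j], disc[best], kf[j],
                                             kf[best])
            score[idx] = relevance[idx] - red_sum[idx] / len(selected)
    if remaining.any():
        rest = np.flatnonzero(remaining)
        rest = rest[np.lexsort((rest, -relevance[rest]))]
        selected.extend(int(j) for j in rest)

    return RankedFeatureList(tuple(selected), tuple(relevance), feature_ids)
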