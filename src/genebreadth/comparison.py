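"""Post-hoc comparison of ranked feature lists and optimum feature sets.

Two analyses: the Jaccard coefficient between the top-k prefixes of two mRMR
lists as a function of k (how much two rankings agree at the top), and the
per-namespace tally (BP / CC / MF / KEGG) of a chosen feature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DomainError
from .io_formats import NAMESPACES, TermCollection
from .mrmr import RankedFeatureList


@dataclass(frozen=True)
class JaccardCurve:
    ks: tuple[int, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.coefficients):
            raise DomainError("ks and coefficients differ in length")
        if any(k < 1 for k in self.ks):
            raise DomainError("k values must be >= 1")
        if any(not 0.0 <= c <= 1.0 for c in self.coefficients):
            raise DomainError("Jaccard coefficients must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "jaccard": self.coefficients})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class NamespaceTally:
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(NAMESPACES):
            raise DomainError(f"counts must cover exactly {NAMESPACES}")
        if any(c < 0 for c in self.counts.values()):
            raise DomainError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"namespace": list(NAMESPACES),
                             "count": [self.counts[ns] for ns in NAMESPACES]})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise DomainError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def topk_jaccard_curve(list_a: RankedFeatureList, list_b: RankedFeatureList,
                       ks: Sequence[int] | None = None) -> JaccardCurve:
    """Jaccard of the two k-prefixes for each k.

    The default k grid is 10, 20, ..., up to the shorter list (mirroring the
    coarse IFS grid); prefixes compare feature ids when both lists carry
    them, otherwise raw indices.
    """
    limit = min(len(list_a), len(list_b))
    if ks is None:
        ks = list(range(10, limit + 1, 10)) or [limit]
    if any(k < 1 or k > limit for k in ks):
        raise DomainError(f"every k must lie in [1, {limit}]")
    use_ids = (list_a.feature_ids is not None
               and list_b.feature_ids is not None)

    def prefix(lst: RankedFeatureList, k: int):
        return set(lst.top_ids(k)) if use_ids else set(lst.top(k))

    coeffs = tuple(jaccard(prefix(list_a, k), prefix(list_b, k)) for k in ks)
    return JaccardCurve(tuple(ks), coeffs)


def namespace_tally(features: Iterable[str],
                    terms: TermCollection) -> NamespaceTally:
    """Count how many of the given feature ids fall in each namespace."""
    counts = {ns: 0 for ns in NAMESPACES}
    for f in features:
        if f not in terms:
            raise DomainError(f"unknown feature id {f!r}")
        counts[terms.namespaces[f]] += 1
    return NamespaceTally(counts)


def plot_jaccard_curve(curve: JaccardCurve, path) -> None:
    """Save a simple line plot of the top-k Jaccard curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.ks, curve.coefficients, marker="o", ms=3)
    ax.set_xlabel("top k features")
    ax.set_ylabel("Jaccard coefficient")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_namespace_tally(tally: NamespaceTally, path) -> None:
    """Save a bar chart of the namespace distribution of a feature set."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(list(NAMESPACES), [tally.counts[ns] for ns in NAMESPACES])
    ax.set_ylabel("features")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
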