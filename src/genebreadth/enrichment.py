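"""PPI-neighborhood enrichment encoding of genes.

Each gene ``g`` is represented by one score per GO term / KEGG pathway: the
-log10 of the hypergeometric upper-tail probability of the overlap between
the gene's PPI neighbor set ``GS(g)`` and the term's annotated gene set.
High scores mean the gene's interaction neighborhood is unexpectedly rich in
genes carrying that annotation, so the vector summarizes the functional
context of a gene rather than its own annotations.

With ``N`` genes in the universe, ``M`` of them annotated to the term,
``n = |GS(g)|`` and overlap ``m``, the score is

    score(g, term) = -log10  sum_{k=m}^{min(n, M)}  C(M,k) C(N-M, n-k) / C(N,n)

i.e. the inclusive upper tail P(X >= m) of Hypergeometric(N, M, n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import DomainError
from .io_formats import PPINetwork, TermCollection

DEFAULT_SCORE_CAP = 300.0


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment encoder.

    universe
        ``"network_nodes"`` (default): the universe is the PPI node set —
        self-consistent with the source of the neighbor sets;
        ``"annotated_union"``: the union of all term gene sets;
        an ``int``: an explicit universe size N (must dominate every M and n).
    score_cap
        Upper bound on scores; p-values that underflow to 0 are reported at
        the cap so features stay bounded for downstream discretization.
    include_self
        Whether a gene belongs to its own neighbor set (default False:
        "interacting genes of g" reads as the neighbors only).
    """

    universe: str | int = "network_nodes"
    score_cap: float = DEFAULT_SCORE_CAP
    include_self: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.universe, str):
            if self.universe not in ("network_nodes", "annotated_union"):
                raise DomainError(f"unknown universe policy {self.universe!r}")
        elif int(self.universe) < 1:
            raise DomainError("explicit universe size must be >= 1")
        if not self.score_cap > 0:
            raise DomainError("score_cap must be > 0")


@dataclass(frozen=True)
class FeatureMatrix:
    """Genes x terms matrix of nonnegative enrichment scores.

    Column order is the collection's canonical order (GO sorted by id, then
    KEGG sorted by id).  Genes whose neighbor set was empty are not present
    as rows; their ids are kept in ``discarded_genes``.
    """

    gene_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    scores: np.ndarray
    discarded_genes: tuple[str, ...] = ()
    config: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.gene_ids), len(self.feature_ids)):
            raise DomainError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.feature_ids)} features")
        if scores.size and (scores.min() < 0 or
                            scores.max() > self.config.score_cap + 1e-12):
            raise DomainError("scores must lie in [0, score_cap]")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def write_tsv(self, path, sidecar: str | None = None) -> None:
        import json

        import pandas as pd

        df = pd.DataFrame(self.scores, index=list(self.gene_ids),
                          columns=list(self.feature_ids))
        df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
        if sidecar is not None:
            cfg = {"universe": self.config.universe,
                   "score_cap": self.config.score_cap,
                   "include_self": self.config.include_self,
                   "discarded_genes": list(self.discarded_genes)}
            with open(sidecar, "w", encoding="utf-8") as fh:
                json.dump(cfg, fh, indent=2)
                fh.write("\n")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=0, index_col=0)
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


def neighbor_set(ppi: PPINetwork, gene: str,
                 config: EnrichmentConfig | None = None) -> set[str]:
    """The gene set GS(g): all genes sharing an edge with ``gene``.

    A gene absent from the network has an empty neighbor set.  With
    ``include_self`` the gene itself is added (only if it is in the network).
    """
    config = config or EnrichmentConfig()
    out = ppi.neighbors(gene)
    if config.include_self and gene in ppi.graph:
        out.add(gene)
    return out


def hypergeom_tail_p(N: int, M: int, n: int, m: int) -> float:
    """Inclusive upper-tail hypergeometric probability P(X >= m).

    X counts the annotated genes in a uniform draw of ``n`` genes from a
    universe of ``N`` containing ``M`` annotated ones.  ``m = 0`` gives 1
    exactly; terms with k > M contribute nothing.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise DomainError(
            f"invalid hypergeometric bounds: N={N}, M={M}, n={n}, m={m}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrichment_score(p: float, config: EnrichmentConfig | None = None) -> float:
    """-log10(p), capped at ``score_cap``; an underflowed p <= 0 maps to the cap."""
    config = config or EnrichmentConfig()
    if p > 1.0:
        raise DomainError(f"p-value {p} above 1")
    if p <= 0.0:
        warnings.warn("p-value underflowed to <= 0; reporting score_cap")
        return config.score_cap
    return min(-np.log10(p), config.score_cap)


def encode_genes(genes: Sequence[str], ppi: PPINetwork, terms: TermCollection,
                 config: EnrichmentConfig | None = None) -> FeatureMatrix:
    """Encode genes as enrichment-score vectors over a term collection.

    Rows cover the input genes whose neighbor set is non-empty, in input
    order; genes with empty neighbor sets carry no enrichment information and
    are discarded (recorded in ``FeatureMatrix.discarded_genes``).  Columns
    follow the collection's canonical term order.
    """
    config = config or EnrichmentConfig()
    if len(terms) == 0:
        raise DomainError("term collection is empty")

    if config.universe == "network_nodes":
        universe = set(ppi.graph.nodes)
    elif config.universe == "annotated_union":
        universe = set(terms.annotated_union())
    else:  # explicit N over the full observed gene space
        universe = set(ppi.graph.nodes) | set(terms.annotated_union())

    uni_index = {g: i for i, g in enumerate(sorted(universe))}
    term_ids = terms.term_ids
    n_terms = len(term_ids)
    membership = np.zeros((n_terms, len(uni_index)), dtype=bool)
    for j, t in enumerate(term_ids):
        for g in terms.gene_sets[t]:
            i = uni_index.get(g)
            if i is not None:
                membership[j, i] = True
    M = membership.sum(axis=1)

    if isinstance(config.universe, int):
        N = int(config.universe)
        if N < len(uni_index):
            raise DomainError(
                f"explicit universe size {N} smaller than the observed gene "
                f"space ({len(uni_index)} genes)")
    else:
        N = len(uni_index)

    kept, kept_rows, discarded = [], [], []
    for g in genes:
        gs = neighbor_set(ppi, g, config)
        gs_idx = [uni_index[x] for x in gs if x in uni_index]
        if not gs_idx:
            discarded.append(g)
            continue
        vec = np.zeros(len(uni_index), dtype=bool)
        vec[gs_idx] = True
        kept.append(g)
        kept_rows.append(vec)
    if not kept:
        raise DomainError("all genes were discarded (empty neighbor sets)")

    gs_matrix = np.array(kept_rows)                       # genes x universe
    n = gs_matrix.sum(axis=1)                             # per gene
    overlap = gs_matrix.astype(np.int64) @ membership.T.astype(np.int64)

    # vectorized inclusive upper tail: sf(m-1); m = 0 handled exactly as p = 1
    with np.errstate(divide="ignore"):
        p = hypergeom.sf(overlap - 1, N, M[np.newaxis, :], n[:, np.newaxis])
        p = np.where(overlap == 0, 1.0, p)
        scores = np.where(p > 0, -np.log10(np.maximum(p, 1e-320)),
                          config.score_cap)
    scores = np.minimum(scores, config.score_cap)
    scores = np.maximum(scores, 0.0)                      # tail p may round >1

    return FeatureMatrix(tuple(kept), term_ids, scores,
                         discarded_genes=tuple(discarded), config=config)
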