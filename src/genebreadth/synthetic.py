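"""Synthetic benchmark generators with planted signal.

Two levels of generator:

* :func:`generate_dataset` builds a whole study-shaped input — an
  Erdős–Rényi-style PPI graph, GO/KEGG-like term collections across the four
  namespaces, and an imbalanced binary gene labeling — and plants signal at
  the *network* level: each positive-class gene gains extra edges into the
  gene sets of a chosen subset of "informative" terms, so its PPI
  neighborhood becomes enriched for those terms exactly the way the encoder
  measures it.
* :func:`generate_feature_matrix` skips the network and emits enrichment-like
  feature columns directly (folded-normal null scores, informative columns
  mean-shifted in the positive class) for unit-level isolation of the
  ranking and selection stages.

Defaults are sized to a desk-scale study: 600 genes, 300 terms over the four
namespaces, 15 informative terms, planted edge probability 0.5, and a
positive:negative imbalance of 4.7 (widely expressed genes outnumber rarely
expressed ones by more than four to one).  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DomainError
from .io_formats import (NEGATIVE, POSITIVE, GeneLabelTable, PPINetwork,
                         TermCollection)


class SyntheticDataset(NamedTuple):
    ppi: PPINetwork
    terms: TermCollection
    labels: GeneLabelTable
    informative_terms: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and effect-size knobs of the network-level generator."""

    n_genes: int = 600
    n_terms: dict = field(default_factory=lambda: {
        "BP": 150, "CC": 60, "MF": 60, "KEGG": 30})
    term_size_range: tuple[int, int] = (10, 40)
    ppi_mean_degree: float = 8.0
    n_informative: int = 15
    effect_strength: float = 0.5
    imbalance: float = 4.7
    seed: int = 0

    def __post_init__(self) -> None:
        total_terms = sum(self.n_terms.values())
        if self.n_genes < 2 or total_terms < 1:
            raise DomainError("n_genes and term counts must be >= 1")
        if set(self.n_terms) - {"BP", "CC", "MF", "KEGG"}:
            raise DomainError("n_terms keys must be BP/CC/MF/KEGG")
        if not 0 < self.term_size_range[0] <= self.term_size_range[1] <= self.n_genes:
            raise DomainError("invalid term_size_range")
        if self.n_informative > total_terms:
            raise DomainError("n_informative exceeds total terms")
        if not 0.0 <= self.effect_strength <= 1.0:
            raise DomainError("effect_strength must be in [0, 1]")
        if self.imbalance <= 0:
            raise DomainError("imbalance must be > 0")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def split_by_imbalance(n: int, imbalance: float) -> tuple[int, int]:
    """Round n * r/(1+r) positives; e.g. n=570 at 4.7:1 gives 470/100."""
    n_pos = int(round(n * imbalance / (1.0 + imbalance)))
    n_pos = min(max(n_pos, 1), n - 1)
    return n_pos, n - n_pos


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate (PPI network, term collection, labels, informative term ids).

    Background edges follow an Erdős–Rényi draw at the configured mean
    degree.  Term gene sets are uniform samples within ``term_size_range``.
    For each positive-class gene and each informative term, an edge to each
    member of the term's gene set is added with probability
    ``effect_strength``; at 0 the construction is an exact null.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n = config.n_genes

    # labels first: the planting step needs them
    n_pos, _ = split_by_imbalance(n, config.imbalance)
    perm = rng.permutation(n)
    is_pos = np.zeros(n, dtype=bool)
    is_pos[perm[:n_pos]] = True
    labels = GeneLabelTable(
        tuple(genes),
        tuple(POSITIVE if p else NEGATIVE for p in is_pos))

    # background Erdős–Rényi graph
    p_edge = min(1.0, config.ppi_mean_degree / (n - 1))
    iu, ju = np.triu_indices(n, k=1)
    background = rng.random(iu.size) < p_edge
    conf = rng.uniform(0.4, 1.0, size=iu.size)
    edge_conf: dict[tuple[int, int], float] = {
        (int(a), int(b)): float(c)
        for a, b, c in zip(iu[background], ju[background], conf[background])}

    # term collections per namespace
    namespaces: dict[str, str] = {}
    gene_sets: dict[str, frozenset[str]] = {}
    members: dict[str, np.ndarray] = {}
    counter = 0
    for ns in ("BP", "CC", "MF", "KEGG"):
        for _ in range(config.n_terms.get(ns, 0)):
            counter += 1
            term = (f"GO:{counter:07d}" if ns != "KEGG"
                    else f"hsa{counter:05d}")
            size = int(rng.integers(config.term_size_range[0],
                                    config.term_size_range[1] + 1))
            idx = rng.choice(n, size=size, replace=False)
            namespaces[term] = ns
            gene_sets[term] = frozenset(genes[i] for i in idx)
            members[term] = np.sort(idx)
    terms = TermCollection(namespaces, gene_sets)

    informative = tuple(sorted(
        np.random.default_rng(config.seed + 1).choice(
            sorted(namespaces), size=config.n_informative, replace=False)))

    # plant signal: positive genes gain edges into informative term sets
    if config.effect_strength > 0:
        pos_idx = np.flatnonzero(is_pos)
        for term in informative:
            tm = members[term]
            hits = rng.random((pos_idx.size, tm.size)) < config.effect_strength
            hit_conf = rng.uniform(0.4, 1.0, size=hits.shape)
            for r, g in enumerate(pos_idx):
                for s, v in enumerate(tm):
                    if hits[r, s] and g != v:
                        key = (min(g, v), max(g, v))
                        prev = edge_conf.get(key)
                        c = hit_conf[r, s]
                        edge_conf[key] = c if prev is None else max(prev, c)

    ppi = PPINetwork.from_edges(
        (genes[a], genes[b], c) for (a, b), c in sorted(edge_conf.items()))
    return SyntheticDataset(ppi, terms, labels, informative)


def generate_feature_matrix(n_samples: int, n_features: int,
                            n_informative: int, shift: float,
                            imbalance: float = 4.7,
                            seed: int = 0):
    """Direct enrichment-like feature matrix with planted informative columns.

    Null scores are folded normal |N(0, 1)| — nonnegative and right-skewed
    like -log10 p-values; informative columns get ``shift`` added in the
    positive class.  Returns ``(FeatureMatrix, GeneLabelTable)``; the
    informative columns are the first ``n_informative`` feature ids.
    """
    from .enrichment import EnrichmentConfig, FeatureMatrix

    if not 0 <= n_informative <= n_features:
        raise DomainError("n_informative must be in [0, n_features]")
    if n_samples < 2:
        raise DomainError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n_pos, _ = split_by_imbalance(n_samples, imbalance)
    y = np.zeros(n_samples, dtype=int)
    y[rng.permutation(n_samples)[:n_pos]] = 1
    scores = np.abs(rng.normal(0.0, 1.0, size=(n_samples, n_features)))
    scores[:, :n_informative] += shift * y[:, np.newaxis]
    gene_ids = tuple(_gene_ids(n_samples))
    feature_ids = tuple(f"T{j:05d}" for j in range(n_features))
    labels = GeneLabelTable(gene_ids,
                            tuple(POSITIVE if v else NEGATIVE for v in y))
    fm = FeatureMatrix(gene_ids, feature_ids, scores,
                       config=EnrichmentConfig(score_cap=float(
                           max(scores.max(), 1.0) + 1.0)))
    return fm, labels
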