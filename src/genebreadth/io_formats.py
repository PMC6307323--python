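"""Readers/writers for the tabular formats the pipeline touches, and the
FPKM-threshold rule that defines the two gene classes.

Formats
-------
* expression TSV: header row of sample ids, first column gene ids, FPKM values;
* label TSV: two columns ``gene_id``, ``label`` (``positive``/``negative``);
* PPI edge TSV: three columns ``gene_a``, ``gene_b``, ``score`` (unit scale or
  the STRING 0-1000 dialect);
* GMT: one term per line, ``term_id <TAB> description <TAB> gene ...``.

Gene identifiers are opaque strings throughout; no symbol/Ensembl mapping is
performed.  All tables are written UTF-8 with LF line endings and header rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
NAMESPACES = ("BP", "CC", "MF", "KEGG")
GO_NAMESPACES = ("BP", "CC", "MF")


# ---------------------------------------------------------------------------
# Expression tables and class labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTable:
    """A genes x samples matrix of nonnegative FPKM values.

    Invariants: unique gene and sample ids, all values finite and >= 0.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError("expression values must be finite (no NaN/inf)")
        if np.any(values < 0):
            raise FormatError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class GeneLabelTable:
    """Binary class assignment: widely expressed = positive, rarely = negative."""

    gene_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene id")
        if len(self.labels) != len(self.gene_ids):
            raise FormatError("labels and gene_ids differ in length")
        bad = sorted({l for l in self.labels} - {POSITIVE, NEGATIVE})
        if bad:
            raise FormatError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def positives(self) -> tuple[str, ...]:
        return tuple(g for g, l in zip(self.gene_ids, self.labels) if l == POSITIVE)

    @property
    def negatives(self) -> tuple[str, ...]:
        return tuple(g for g, l in zip(self.gene_ids, self.labels) if l == NEGATIVE)

    def y(self, gene_order: Sequence[str] | None = None) -> np.ndarray:
        """0/1 vector (1 = positive) aligned to ``gene_order`` (default: own order)."""
        mapping = dict(zip(self.gene_ids, self.labels))
        order = self.gene_ids if gene_order is None else tuple(gene_order)
        missing = [g for g in order if g not in mapping]
        if missing:
            raise DomainError(f"genes without labels: {missing[:5]}...")
        return np.array([1 if mapping[g] == POSITIVE else 0 for g in order],
                        dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.gene_ids),
                             "label": list(self.labels)})


def read_expression_table(path) -> ExpressionTable:
    """Read a genes x samples FPKM TSV (header = sample ids, column 1 = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"expression file has no sample columns: {path}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate gene id(s) in {path}: {dup}")
    if df.isna().any().any():
        raise FormatError(f"missing value(s) in expression file {path}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in expression file {path}: {exc}") from exc
    return ExpressionTable(tuple(df.index.astype(str)),
                           tuple(df.columns.astype(str)), values)


def write_expression_table(expr: ExpressionTable, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id",
                           lineterminator="\n")


def label_genes_by_expression(expr: ExpressionTable,
                              threshold: float = 1.0) -> GeneLabelTable:
    """Assign the two expression-breadth classes by a strict FPKM threshold.

    A gene is *positive* (widely expressed) iff its FPKM exceeds ``threshold``
    in every sample and *negative* (rarely expressed) iff it is below the
    threshold in every sample.  Genes matching neither pattern — including any
    gene with a value exactly equal to the threshold — are omitted.
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold}")
    if expr.n_genes == 0:
        raise DomainError("cannot label an empty expression table")
    pos = np.all(expr.values > threshold, axis=1)
    neg = np.all(expr.values < threshold, axis=1)
    genes, labels = [], []
    for g, p, n in zip(expr.gene_ids, pos, neg):
        if p:
            genes.append(g)
            labels.append(POSITIVE)
        elif n:
            genes.append(g)
            labels.append(NEGATIVE)
    return GeneLabelTable(tuple(genes), tuple(labels))


def read_gene_labels(path) -> GeneLabelTable:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty label file: {path}") from exc
    if list(df.columns[:2]) != ["gene_id", "label"]:
        raise FormatError(
            f"label file must have columns gene_id, label; got {list(df.columns)}")
    return GeneLabelTable(tuple(df["gene_id"]), tuple(df["label"]))


def write_gene_labels(labels: GeneLabelTable, path) -> None:
    labels.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI graph with edge confidences in [0, 1].

    Thin wrapper over :class:`networkx.Graph`; no self-loops, duplicate pairs
    collapsed keeping the maximum confidence.
    """

    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="confidence"):
            if u == v:
                raise FormatError(f"self-loop on {u}")
            if w is None or not (0.0 <= w <= 1.0):
                raise FormatError(f"edge ({u},{v}) confidence {w} outside [0,1]")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                warnings.warn(f"dropping self-loop on {a}")
                continue
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], float(w))
            else:
                g.add_edge(a, b, confidence=float(w))
        return cls(g)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, w in self.graph.edges(data="confidence"):
            a, b = sorted((u, v))
            out.append((a, b, w))
        return sorted(out)


def read_ppi_edges(path, min_confidence: float = 0.0,
                   scale: str = "unit") -> PPINetwork:
    """Read a 3-column edge TSV into a :class:`PPINetwork`.

    ``scale="string_1000"`` divides scores by 1000 (the STRING dialect);
    ``scale="unit"`` takes them as already in [0, 1].  Edges below
    ``min_confidence`` (after normalization) are removed; the default 0 keeps
    every edge, as no confidence cutoff is assumed.
    """
    if scale not in ("unit", "string_1000"):
        raise DomainError(f"unknown scale {scale!r}")
    if not (0.0 <= min_confidence <= 1.0):
        raise DomainError(f"min_confidence must be in [0,1], got {min_confidence}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty PPI file: {path}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"PPI file needs 3 columns (gene_a, gene_b, score): {path}")
    scores = df.iloc[:, 2].astype(float).to_numpy()
    if np.any(scores < 0):
        raise FormatError(f"negative interaction score in {path}")
    if scale == "string_1000":
        scores = scores / 1000.0
    if np.any(scores > 1.0):
        raise FormatError(
            f"score above 1 after normalization in {path}; wrong scale flag?")
    edges = [(a, b, s) for a, b, s in
             zip(df.iloc[:, 0], df.iloc[:, 1], scores) if s >= min_confidence]
    return PPINetwork.from_edges(edges)


def write_ppi_edges(ppi: PPINetwork, path) -> None:
    df = pd.DataFrame(ppi.edge_list(), columns=["gene_a", "gene_b", "score"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Term collections (GO / KEGG gene sets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermCollection:
    """Flat gene-set annotations: term id -> (namespace, annotated genes).

    Namespaces are the three GO branches (BP, CC, MF) plus KEGG.  Terms are
    treated as flat sets; no ontology propagation is applied.
    """

    namespaces: Mapping[str, str]
    gene_sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.namespaces) != set(self.gene_sets):
            raise FormatError("namespaces and gene_sets must cover the same terms")
        for term, ns in self.namespaces.items():
            if ns not in NAMESPACES:
                raise FormatError(f"term {term}: unknown namespace {ns!r}")
            if not self.gene_sets[term]:
                raise FormatError(f"term {term}: empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __contains__(self, term: str) -> bool:
        return term in self.gene_sets

    @property
    def term_ids(self) -> tuple[str, ...]:
        """GO terms (sorted by id) first, then KEGG (sorted by id)."""
        go = sorted(t for t, ns in self.namespaces.items() if ns in GO_NAMESPACES)
        kegg = sorted(t for t, ns in self.namespaces.items() if ns == "KEGG")
        return tuple(go + kegg)

    def annotated_union(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.gene_sets.values():
            out |= gs
        return frozenset(out)

    def merge(self, other: "TermCollection") -> "TermCollection":
        overlap = set(self.namespaces) & set(other.namespaces)
        if overlap:
            raise FormatError(f"duplicate term id(s) on merge: {sorted(overlap)[:5]}")
        return TermCollection({**self.namespaces, **other.namespaces},
                              {**self.gene_sets, **other.gene_sets})


def read_gmt(path, namespace: str | None = None) -> TermCollection:
    """Read a GMT file into a :class:`TermCollection`.

    ``namespace`` applies to every term in the file; if omitted, the GMT
    description field must itself be one of BP/CC/MF/KEGG.  Terms with no
    genes are dropped with a logged warning; duplicate term ids are an error.
    """
    namespaces: dict[str, str] = {}
    gene_sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 2 fields")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if term in namespaces:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term}")
            if not genes:
                logger.warning("%s:%d: term %s has no genes; dropped",
                               path, lineno, term)
                continue
            ns = namespace if namespace is not None else desc
            if ns not in NAMESPACES:
                raise FormatError(
                    f"{path}:{lineno}: namespace {ns!r} not one of {NAMESPACES}")
            namespaces[term] = ns
            gene_sets[term] = genes
    return TermCollection(namespaces, gene_sets)


def write_gmt(terms: TermCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in terms.term_ids:
            genes = sorted(terms.gene_sets[term])
            fh.write("\t".join([term, terms.namespaces[term], *genes]) + "\n")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i}")
        seen.add(i)
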