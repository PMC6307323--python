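"""End-to-end orchestration: label -> encode -> rank -> IFS -> report.

:func:`run_pipeline` chains the library stages on files, writes every
intermediate artifact into an output directory, and records a manifest with
versions, per-stage seeds and SHA-256 checksums so a rerun with the same
config is byte-checkable.  One global seed derives the per-stage seeds by
fixed offsets (single-knob reproducibility).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classifiers import ClassifierSpec
from .comparison import namespace_tally
from .enrichment import EnrichmentConfig, encode_genes
from .errors import DomainError
from .ifs import run_ifs
from .io_formats import (GeneLabelTable, read_expression_table,
                         read_gene_labels, read_gmt, read_ppi_edges,
                         label_genes_by_expression, write_gene_labels)
from .metrics import write_metrics_table
from .mrmr import mrmr_rank

logger = logging.getLogger(__name__)

# fixed offsets from the global seed, one per stochastic stage
SEED_OFFSETS = {"classifier": 1, "folds": 2}


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs of a full pipeline run.

    Labels come either from ``labels_path`` directly or from
    ``expression_path`` via the FPKM threshold rule.  ``gmt_paths`` maps each
    GMT file to its namespace (or ``None`` to read the namespace from the
    description field).
    """

    ppi_path: str
    gmt_paths: dict
    out_dir: str
    labels_path: str | None = None
    expression_path: str | None = None
    fpkm_threshold: float = 1.0
    min_confidence: float = 0.0
    ppi_scale: str = "unit"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    n_bins: int = 4
    engine: str = "random_forest"
    engine_hyperparameters: dict = field(default_factory=dict)
    step: int = 10
    width: int = 50
    folds: int = 10
    interval: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.labels_path is None) == (self.expression_path is None):
            raise DomainError(
                "exactly one of labels_path / expression_path must be given")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = [config.ppi_path] + list(config.gmt_paths)
    inputs.append(config.labels_path or config.expression_path)
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise DomainError(f"missing input path(s): {missing}")

    logger.info("stage label: reading inputs")
    ppi = read_ppi_edges(config.ppi_path, config.min_confidence,
                         config.ppi_scale)
    terms = None
    for path, ns in config.gmt_paths.items():
        coll = read_gmt(path, namespace=ns)
        terms = coll if terms is None else terms.merge(coll)
    if config.labels_path is not None:
        labels = read_gene_labels(config.labels_path)
    else:
        expr = read_expression_table(config.expression_path)
        labels = label_genes_by_expression(expr, config.fpkm_threshold)
    labels_out = out / "labels.tsv"
    write_gene_labels(labels, labels_out)

    logger.info("stage encode: %d genes x %d terms", len(labels), len(terms))
    fm = encode_genes(list(labels.gene_ids), ppi, terms, config.enrichment)
    kept = GeneLabelTable(
        fm.gene_ids,
        tuple(dict(zip(labels.gene_ids, labels.labels))[g]
              for g in fm.gene_ids))
    matrix_out = out / "feature_matrix.tsv"
    fm.write_tsv(matrix_out, sidecar=str(out / "feature_matrix.config.json"))

    logger.info("stage rank: mRMR over %d features", fm.n_features)
    ranked = mrmr_rank(fm, kept, n_bins=config.n_bins)
    ranked_out = out / "ranked.tsv"
    ranked.write_tsv(ranked_out)

    logger.info("stage ifs: engine=%s step=%d width=%d folds=%d",
                config.engine, config.step, config.width, config.folds)
    spec = ClassifierSpec(config.engine,
                          seed=config.seed + SEED_OFFSETS["classifier"],
                          hyperparameters=config.engine_hyperparameters)
    result = run_ifs(fm, kept.y(fm.gene_ids), ranked, spec,
                     step=config.step, width=config.width,
                     folds=config.folds,
                     seed=config.seed + SEED_OFFSETS["folds"],
                     interval=config.interval)

    stage1_out = out / "stage1.tsv"
    stage2_out = out / "stage2.tsv"
    write_metrics_table([(r.n_features, r.metrics) for r in result.stage1],
                        stage1_out)
    write_metrics_table([(r.n_features, r.metrics) for r in result.stage2],
                        stage2_out)
    opt = result.optimum_metrics
    optimum_out = out / "optimum.json"
    with open(optimum_out, "w", encoding="utf-8") as fh:
        json.dump({"optimum_size": result.optimum_size,
                   "interval": list(result.interval),
                   "metrics": {"SN": opt.SN, "SP": opt.SP, "ACC": opt.ACC,
                               "MCC": opt.MCC, "J": opt.J}}, fh, indent=2)
        fh.write("\n")
    model_out = out / "optimum_model.joblib"
    result.optimum_classifier.save(model_out)

    logger.info("stage compare: namespace tally of the optimum feature set")
    opt_ids = ranked.top_ids(result.optimum_size)
    tally = namespace_tally(opt_ids, terms)
    tally_out = out / "namespace_tally.tsv"
    tally.write_tsv(tally_out)

    artifacts = {
        "labels": labels_out, "feature_matrix": matrix_out,
        "feature_matrix_config": out / "feature_matrix.config.json",
        "ranked": ranked_out, "stage1": stage1_out, "stage2": stage2_out,
        "optimum": optimum_out, "namespace_tally": tally_out,
    }
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {k: config.seed + v for k, v in SEED_OFFSETS.items()},
        "engine": config.engine,
        "optimum_size": result.optimum_size,
        "optimum_youden": opt.J,
        "discarded_genes": list(fm.discarded_genes),
        "model": str(model_out),
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in artifacts.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
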