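"""End-to-end run: synthetic study -> encode -> mRMR -> two-step IFS.

Generates a network-level synthetic study (positive-class genes gain extra
PPI edges into 8 informative term gene sets), encodes all genes, ranks the
term features, and runs the two-step incremental feature selection with a
cross-validated random forest, selecting the prefix size that maximizes
Youden's index J = SN + SP - 1.
"""

import genebreadth as gb

cfg = gb.SyntheticConfig(
    n_genes=300, n_terms={"BP": 50, "CC": 20, "MF": 20, "KEGG": 10},
    n_informative=8, effect_strength=0.5, imbalance=4.7, seed=5)
ds = gb.generate_dataset(cfg)
print(f"{len(ds.labels.positives)} positive / "
      f"{len(ds.labels.negatives)} negative genes, "
      f"{len(ds.terms)} terms ({len(ds.informative_terms)} informative)")

fm = gb.encode_genes(list(ds.labels.gene_ids), ds.ppi, ds.terms)
y = ds.labels.y(fm.gene_ids)
ranked = gb.mrmr_rank(fm, ds.labels)
hits = set(ranked.top_ids(16)) & set(ds.informative_terms)
print(f"informative terms recovered in mRMR top 16: {len(hits)}/8")

spec = gb.ClassifierSpec("random_forest", seed=2,
                         hyperparameters={"n_estimators": 50})
res = gb.run_ifs(fm, y, ranked, spec, step=10, width=10, folds=10, seed=3)
m = res.optimum_metrics
print(f"stage-2 interval: {res.interval}")
print(f"optimum prefix size: {res.optimum_size}")
print(f"SN={m.SN:.3f} SP={m.SP:.3f} ACC={m.ACC:.3f} "
      f"MCC={m.MCC:.3f} J={m.J:.3f}")
# The optimum J is the maximum cross-validated Youden index over every
# evaluated prefix of the mRMR list; a J near 1 means the planted network
# signal is fully recoverable from the enrichment encoding.
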