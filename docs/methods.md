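# Methods

## Problem and model

The package frames expression breadth as a binary classification problem:
*widely expressed* genes (FPKM strictly above a threshold in every sample)
against *rarely expressed* genes (strictly below it in every sample). Genes
whose profile matches neither pattern — including any value exactly at the
threshold — are excluded rather than forced into a class, because the strict
two-sided rule leaves their breadth undefined. The labeling is equivariant
under joint rescaling of the FPKM matrix and the threshold.

Each gene is represented not by its own annotations but by the functional
composition of its PPI neighborhood. For gene *g* with neighbor set GS(*g*)
(the genes sharing an edge with *g*; the gene itself is excluded by default)
and a term with annotated set of size *M* inside a universe of *N* genes,
the feature value is the −log₁₀ of the inclusive hypergeometric upper tail
P(X ≥ m) at the observed overlap *m* with n = |GS(g)| draws. The encoding
therefore asks, term by term, "is this gene's interaction neighborhood
richer in this annotation than chance?" and uses the answer's significance
as a continuous, robust feature. No ontology propagation is applied: terms
are flat sets, and scores are features rather than inferences, so no
multiple-testing correction is involved.

## Numerical and design choices

* **Universe size N.** Default: the PPI node set, which is self-consistent
  with the source of the neighbor sets. Alternatives: the union of all
  annotated genes, or an explicit N (validated to dominate every M and n).
  Term sets are always intersected with the universe before M is computed,
  so M ≤ N holds by construction.
* **Tail convention.** Inclusive upper tail P(X ≥ m), computed by
  `scipy.stats.hypergeom.sf(m−1, N, M, n)`; m = 0 returns exactly 1 (score
  0). Stable for N up to at least 10⁵.
* **Score cap.** P-values below ~1e−300 underflow; such scores are reported
  at the cap (default 300) so features stay bounded for discretization.
* **Feature order.** GO terms sorted by id, then KEGG sorted by id; the
  order is recorded in the matrix header.
* **Genes without neighbors** carry no enrichment information and are
  discarded from the matrix (reported in `discarded_genes`).

### mRMR

Continuous scores are discretized into equal-frequency bins (default 4, a
standard choice balancing resolution against contingency-table sparsity)
and mutual information is the plug-in estimate in nats; the MI base rescales
relevance and redundancy jointly and cannot change the ranking. The greedy
selection caches redundancy sums incrementally — each step costs one MI
evaluation per remaining feature — and is provably identical to naive
recomputation (tested against an exhaustive oracle). Ties on D − R break to
the lowest original index for determinism. `max_rank_depth` ranks only a
prefix greedily and appends the remainder by descending relevance, for use
when downstream scans never reach deeper prefixes.

### Classifier engines

The LSTM consumes the feature vector as a sequence of fixed-size chunks
(default 32 scalars per timestep, last chunk zero-padded) — a standard way
to feed a fixed-length vector to a recurrent model. Gates follow the
conventional equations with h_t = o_t ⊙ tanh(c_t); one printed source of
these equations circulates with a self-referential last line
(tanh of h_t), which is treated as a typo for tanh(c_t). Training is
full-batch Adam (lr 0.02, 200 epochs, hidden 16, forget-gate bias 1,
1/√fan-in Gaussian init) on binary cross-entropy over a linear readout of
h_T; full-batch updates plus a seeded generator make fits exactly
reproducible. Inputs are column-standardized inside the classifier to keep
gate pre-activations in range. The decision threshold is 0.5 on the
positive-class probability (logit 0 counts as positive); class weighting is
deliberately off, reproducing the characteristic SP ≪ SN behavior on
imbalanced data. The random-forest engine wraps scikit-learn
(`n_estimators` configurable, seeded, single-threaded).

### Cross-validation and measures

10-fold CV by default, stratified by class — with ~4.7:1 imbalance,
unstratified folds of a small study can lose the negative class entirely;
an unstratified flag exists. Held-out predictions are pooled into one
confusion table per model (so each evaluated model yields a single
SN/SP/ACC/MCC/J record rather than fold-averaged values). MCC returns 0
when any denominator factor vanishes. Youden's J = SN + SP − 1 is the
selection criterion because it is insensitive to prevalence.

### Two-step IFS

Stage 1 evaluates prefix sizes step, 2·step, … (default step 10, plus the
full size if not a multiple); stage 2 evaluates every size in
[best − width, best + width] clipped to [1, N] (default width 50, with an
explicit-interval override for replicating hand-chosen windows). A single
fold assignment is reused across all sizes so curves are comparable; sizes
shared by both stages are computed once. The optimum is the global Youden
argmax, ties to the smaller size.

## The synthetic generator

`generate_dataset` emulates the statistical shape of a real study: an
Erdős–Rényi background PPI graph (default mean degree 8, uniform [0.4, 1)
confidences), term collections across BP/CC/MF/KEGG (default
150/60/60/30 terms of 10–40 genes), binary labels at a 4.7:1
positive:negative ratio, and a planted effect — each positive-class gene
gains an edge to each member of each informative term's gene set with
probability `effect_strength`. Planting at the network level means the
encoder itself (neighbor sets, tail probabilities) is exercised exactly as
on real data, and `effect_strength = 0` is an exact null in which the two
classes are statistically identical.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real PPI networks, the GO DAG and its annotation
inheritance, correlated term memberships, and biological confounding
between degree and expression breadth. One consequence of the planted
design is that positive genes acquire higher degree, so even non-informative
terms carry weak class signal through neighbor-set size; passing recovery
tests therefore demonstrates that the chain recovers planted network signal,
not that real widely/rarely expressed genes are separable at any particular
accuracy. `generate_feature_matrix` skips the network and draws
folded-normal |N(0,1)| null scores (nonnegative and right-skewed, like
−log₁₀ p-values) with a mean shift on informative columns in the positive
class, for unit-level isolation of ranking and selection.

## Problem sizes used in tests and the acceptance script

End-to-end runs use the generator defaults (600 genes, 300 terms, 15
informative, effect 0.5, imbalance 4.7) with the random-forest engine (50
trees), step 10, stage-2 width 25, 10-fold CV; these sizes keep a full run
to roughly a minute while leaving the planted signal comfortably
recoverable. The LSTM engine is exercised end-to-end on a smaller
well-separated problem (300 samples, 10 features). The null-safety check
aggregates the optimum Youden over 5 seeds by its mean: the optimum is a
maximum over ~80 evaluated prefix sizes, so individual seeds carry a small
positive selection bias even under a perfect null.

## Pipeline and reproducibility

`run_pipeline` chains the stages on files, writes eight artifacts (labels,
feature matrix + config sidecar, ranked list, stage-1/stage-2 curves,
optimum summary, namespace tally) plus a fitted-model container and a
manifest with SHA-256 checksums; a rerun with the same config reproduces
identical checksums. One global seed derives per-stage seeds by fixed
offsets. All randomness flows through `numpy.random.default_rng` with
integer seeds and order-stable iteration, so outputs are identical across
platforms.

## Known limitations

* The LSTM is single-layer and CPU-only; no hyperparameter search is
  provided, and on strongly imbalanced data it can collapse to the majority
  class when the signal is weak (mitigated only by feature selection, by
  design).
* The mRMR difference criterion (D − R) can interleave irrelevant features
  between correlated informative ones; the quotient variant is deliberately
  not implemented.
* Enrichment features are computed from a single static network; no
  confidence weighting is used beyond the optional edge filter.
* The expression labeler rejects missing values rather than imputing: the
  strict all-samples rule is undefined on incomplete profiles.
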