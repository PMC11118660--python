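# Methods

## Overview

`hetdr` predicts binary drug sensitivity of cancer cell lines and ranks
drug–gene associations by attention. The data model is a heterogeneous graph
with three node types — drugs, cell lines, genes — and three edge types:

* **drug–cell** (`Adc`): binary sensitive-response associations derived from
  an IC50 screen;
* **cell–gene** (`Acg`): above-average expression, the positive part of
  per-gene z-scores;
* **drug–gene** (`Adg`): curated drug–target interactions (DTIs) over a
  configurable pad for unknown pairs (0 = absent, 0.5 = unknown).

A multi-head graph-transformer (GT) stack learns node embeddings from this
graph; a drug–cell pair is scored by concatenating the two embeddings and
passing them through fully connected layers with a sigmoid output. The
attention coefficients of the trained model, head-averaged and layer-summed,
are read out as drug–gene association scores.

## Preprocessing

IC50 values are log10-transformed and filtered per drug to the central
95% band (linear-interpolation percentiles, inclusive bounds). Remaining
values are z-scored per drug and labeled **sensitive** (1) when
x < μ − σ, **resistant** (0) when x > μ + σ, and **uncertain** otherwise;
uncertain pairs never enter training or evaluation. The sample standard
deviation (ddof = 1) is used throughout. Zero-variance or near-empty drug
rows produce all-uncertain labels with a warning rather than an error, so
sparse screens do not abort a run.

Gene selection keeps the top fraction of genes by expression standard
deviation (10% is the customary setting for transcriptome-wide panels; the
synthetic screens here keep all genes) united with all genes appearing in
the DTI table.

Node features are RBF-kernel similarity matrices,
S_ij = exp(−γ‖x_i − x_j‖²) with γ = 1/d for d features: drug–drug similarity
from 2048-bit Morgan fingerprints, cell–cell and gene–gene similarity from
the expression matrix and its transpose.

## Model

Each entity's similarity matrix passes through its own linear layer into a
shared hidden space; the rows are stacked (drugs, then cells, then genes)
into the unified feature matrix X. Each of `n_gnn_layers` blocks computes

    Z = Dropout(ReLU(GraphNorm(GT(X, A))))

where GT is multi-head dot-product attention restricted to graph
neighborhoods with a root/skip weight, and GraphNorm is graph normalization
(learnable mean-shift α, scale γ, bias β per feature, statistics over all
nodes). Head outputs are concatenated and linearly mixed back to
`hidden_size`.

Edge weights enter the attention softmax multiplicatively:

    α_ij = w_ij · exp(s_ij) / Σ_k w_ik · exp(s_ik),   s = QKᵀ/√D,

so a zero weight excludes a pair, positive weights bias attention, and each
node's incoming attention still sums to one per head. Every node carries a
unit self-loop so isolated nodes (e.g. a fully masked cold-start drug under
zero padding) have a well-defined neighborhood.

The implementation is dense: attention is computed as masked N × N
matrices, which at the package's design scale (hundreds to a few thousand
nodes) is substantially faster than edge-list gather/scatter and keeps the
whole model inside ordinary BLAS calls. Automatic differentiation is
provided by a small reverse-mode engine (`hetdr.autodiff`) whose every
operator is validated against central finite differences in the test suite.

### Numerical choices

* Softmax numerators are computed as w·exp(s − max_edges s) in one fused
  operation; the row maximum is taken over edge positions only and treated
  as a constant.
* BCE probabilities are clamped to [1e−7, 1 − 1e−7].
* Similarity features are column-standardized before projection
  (`standardize_features`, default on). RBF similarities concentrate near 1,
  so raw projected features start nearly collinear; centering is absorbed
  into the affine projection's function class but markedly improves
  conditioning and training speed.
* Dropout applies to node features after ReLU (rate `dropout_rate`) and to
  normalized attention coefficients (`attn_dropout`, TransformerConv-style
  normalize-then-drop). Attention dropout is the decisive regularizer on
  small screens: without it the model memorizes training edges through the
  attention pattern and generalizes poorly.
* Full-batch Adam; training is single-threaded deterministic given
  (config, seed).

### Defaults

| parameter | default | note |
|---|---|---|
| hidden_size | 120 | divisible by n_heads |
| n_heads | 5 | fixed head count of the interpretability analyses |
| n_gnn_layers | 2 | two hops: drug→gene→cell paths |
| n_fc_layers | 2 | hidden→hidden→1 head |
| dropout_rate | 0.2 | feature dropout |
| attn_dropout | 0.3 | attention-coefficient dropout |
| learning_rate | 0.005 | Adam |
| weight_decay | 1e-4 | Adam L2 |
| epochs | 300 | full-batch |

Defaults were chosen by a small validation grid on held-out folds of a
synthetic screen (`hetdr.grid.grid_search` replaces a full hyperparameter
search, which is out of scope at desk scale). Held-out AUROC on those folds
rises slowly up to roughly 500 epochs and then plateaus; 300 epochs is the
package's standard schedule, and the leave-one-out protocol — whose
per-target training sets are nearly the full screen — uses a shorter
150-epoch schedule with a comfortable validated margin.

## Evaluation protocols

**Random masking.** Labeled drug–cell pairs are shuffled (seeded) into k
near-equal folds. For each fold the test pairs are hidden from `Adc` by a
Hadamard mask before graph assembly, the model is retrained from scratch,
and the hidden pairs are scored. Leakage is structurally impossible:
the training-time graph is bit-identical under arbitrary changes to
held-out labels, and the suite asserts this.

**Leave-one-out (cold start).** Every labeled pair of a held-out drug (or
cell line) is hidden and scored after retraining. Targets are screened
first: at least 10 labeled pairs and at least 2% of each class. Prediction
for the held-out entity flows only through its features (fingerprint
similarity for drugs) and its unmasked graph edges (known DTIs).

**Metrics.** AUROC is the Mann–Whitney statistic (ties half credit); AUPR is
average precision (step-wise PR integral); both via scikit-learn and
cross-checked in the suite against exhaustive pair counting and a naive PR
traversal. Per-fold/per-target results are aggregated by unweighted mean ± sd.
Metrics are undefined for single-class targets; such units are skipped with
a warning (the eligibility screen makes this rare).

### Padding mode

Whether unknown drug–gene pairs are padded with 0 or 0.5 is a model
hyperparameter. On large real screens zero padding has the edge for pure
prediction, and interpretability analyses use soft padding so attention can
diffuse beyond annotated targets. On the synthetic screens used here, where
half the true DTIs are hidden from the model, soft padding is also the
better predictor — the drug→gene attention path over unannotated pairs is
precisely what recovers the hidden mechanism — so the package defaults to
soft padding for its benchmark runs and exposes `pad_mode` everywhere.

## Attention interpretation

Attention tensors are captured on a dedicated eval-mode forward pass after
training (dropout-free). Within each layer heads are averaged; layers are
then summed. The drug–gene slice can be read in either direction; the
default (`gene_receives`) uses the attention each gene node pays to drug
sources, transposed to drugs × genes. The rationale: a gene's softmax runs
over its own neighborhood and so directly contrasts which drugs inform that
gene's representation, whereas a drug's softmax over hundreds of gene
neighbors mixes in the first layer's structurally uninformative drug→gene
attention (before any message passing, a drug's features carry no
information about specific genes). The drug-side view remains available via
`direction="drug_receives"`. The slice is ranked per drug; ties break
lexicographically by gene id, and genes with no connectivity are never
ranked. Associations found in the training DTI
table are labeled `known_dti`, the rest `novel`; the DTI recovery fraction
is reported against the visible DTI table.

Over-representation analysis: for each drug the top-q attention genes
(q = 100 by default) are tested against a GMT gene-set collection with the
hypergeometric upper tail P(X ≥ overlap) over a configurable universe
(default: the graph's gene set). Benjamini–Hochberg adjustment is applied
within each drug's family of tested sets (a `global` family is available);
adjusted p < 0.05 flags significance. Offline literature support is
computed by counting abstracts that co-mention a drug and a gene in a
user-supplied abstract index (no live queries).

## Synthetic cohorts

The generator plants a known mechanism so that recovery can be scored
exactly. Drugs are grouped into mechanisms (default: pairs); each mechanism
owns `targets_per_drug` dedicated target genes. Expression is Gaussian per
gene with lognormal spread. A cell's latent sensitivity to a drug is
`effect_size` times its standardized target expression; observed response is
IC50 = 10^(−latent + ε), ε ~ N(0, noise_sd), so the standard preprocessing
chain applies unchanged. Fingerprints share a per-mechanism bit block plus
random background bits, giving cold-start prediction a structure-to-
mechanism path. A seeded fraction of the planted drug–target pairs is
exposed as the known DTI table (`dti_visible_fraction`, default 0.5).

Default study conditions: 40 drugs, 30 cell lines, 200 genes, 1 target per
drug, effect size 2.0, noise sd 0.5. Under the μ ± σ margin roughly a third
of pairs receive labels (~10 per drug), so about half the drugs clear the
10-entry cold-start screen per cohort; cold-start summaries therefore
accumulate cohort replicates until at least 20 eligible drugs are evaluated.

What the generator does **not** emulate: drug- or cell-level main effects
(broadly toxic drugs, broadly resistant lines), correlated expression
programs, assay batch structure, or realistic marginal IC50 distributions.
The planted signal is purely interaction-shaped, which makes the benchmark
*harder* than real screens for main-effect-exploiting models; passing tests
demonstrate mechanism recovery, not real-data performance.

## Known limitations

* Dense N × N attention bounds practical graphs to a few thousand nodes.
* Full-batch training only; no mini-batching or GPU path.
* The GT layer is the only message-passing variant implemented; the layer
  interface is pluggable but GCN/GAT variants are not shipped.
* Retraining per held-out target makes leave-one-out linear in the number
  of eligible targets.
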