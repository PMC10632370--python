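# Methods

`corelearn` implements a positive-unlabeled (PU) ensemble for prioritizing
*core* disease genes — genes whose function directly and mechanistically
influences a phenotype under the omnigenic view — from typed molecular
networks and gene-level numeric features, trained on a small set of strong
positive labels (e.g. Mendelian disorder genes) with no verified negatives.

## Data model

Genes form an ordered universe shared by all networks. Protein–protein
interaction networks are undirected and stored with both edge directions;
gene-regulatory networks keep only the TF→target orientation. Edges are typed
by source network; the same gene pair may be connected once per network.
Isolated genes stay in the universe and are convolved with themselves through
the self-loop added inside the spectral layers. Genes with any missing
feature are excluded, so the universe is feature-driven. Features are scaled
per column to `(x − median)/IQR` with linearly interpolated quantiles;
zero-IQR columns are centered only.

## Base classifiers

All classifiers except LINKX share a three-block architecture: a
pre-message-passing MLP (two hidden dense layers, ELU activations, hidden
dimension 50 by default), a stack of two message-passing layers (each
followed by ELU and instance normalization without learned affine,
ε = 1e-5), and a post-message-passing MLP ending in a single sigmoid output
per gene. Message-passing kinds:

- **GCN** — `X' = D^{-1/2}(A+I)D^{-1/2} X W` with D the degree matrix of
  A+I; single edge type.
- **TAG** — `Σ_{k=0..K} Â^k X W_k`, default K = 3; the k = 0 term is a skip
  connection.
- **RGCN** — per-relation mean-normalized neighborhoods plus a root
  transform: `x'_v = W_root x_v + Σ_r Σ_{u∈N_r(v)} W_r x_u / |N_r(v)|`.
- **FiLM** — per-relation messages `relu(γ_{r,v} ⊙ W_r x_u + β_{r,v})`
  summed *without* degree normalization (the relational layers are
  implemented exactly as their update rules are written, which leaves this
  asymmetry with RGCN in place). The receiver-conditioned (β, γ) pair comes
  from a one-layer hypernetwork; its bias is initialized to β = 0, γ = 1 so
  messages pass at initialization. The rectifier is used inside the message;
  ELU only between dense layers.
- **MLP** — message passing disabled; ignores the graph entirely.
- **N2V+MLP** — an MLP over the concatenation of features and a
  100-dimensional unsupervised random-walk embedding of the merged
  (type-free) network union. Walks are unbiased (return and in-out
  parameters 1, as no bias setting is adopted); a skip-gram model with five
  negative samples per pair is trained on co-occurrence pairs within a
  window of 5. Nodes never appearing in a pair receive zero vectors.
- **LINKX** — separate MLPs over dense adjacency rows and features joined by
  a third MLP; the first adjacency-branch weight matrix carries an L1
  penalty with α = 1e-2 added to the training loss.

Every layer accepts an optional per-edge weight that scales messages
multiplicatively; weight 1 is a no-op, weight 0 removes the edge. This is
the hook that makes edge attribution well-defined for all classifier kinds.

Because no GPU tensor framework is assumed, the layers run on a small
reverse-mode automatic-differentiation engine over NumPy arrays
(`corelearn.autodiff`) providing exactly the operations the architectures
need, including gather/scatter for sparse message passing. Gradients flow to
weights (training) and to features and edge weights (attribution). All
computation is single-threaded and bit-reproducible under a seed.

## PU training

Unlabeled genes are treated as class 0, with two corrections: *dilution*
resamples, fresh each epoch, `|P_train|·d` unlabeled genes uniformly with
replacement (d = 10), so unlabeled genes resembling positives are not
penalized every step and class imbalance is removed; *amplification*
multiplies the positive BCE term by a = 2, making false negatives twice as
costly as false positives. Scores are clamped at 1e-7 to keep BCE finite.
Optimization is full-batch Adam at learning rate 1e-3 (the graph fits in
memory at the scales targeted here), up to 1000 epochs. Early stopping
monitors F1 = 2·pr·rec/(pr+rec), with precision computed on the training
universe (training positives vs all training negatives) and recall on a
positives-only holdout, both after binarizing at score > 0.7 (strict
inequality). Improvement is strict; training stops 100 epochs after the best
monitor and the best-epoch weights are restored. The printed form of the
monitor omits the harmonic-mean denominator in some descriptions of this
design; the standard F-measure is used here as the interpretable,
monotone-comparable choice.

Method selection uses a 4-fold × 4-repeat cross validation (16 models), each
fold holding out 25% of positives and unlabeled genes, scoring mean AUROC on
the holdout with unlabeled treated as negatives.

## Nested ensemble and the inner threshold

The ensemble is an m × n nested cross validation over the positives
(defaults m = 11, n = 10, configurable so tests can shrink it). Outer fold j
holds out test_j (≈ 9% of positives at m = 11); the conservative holdout
scheme relabels test_j as negatives during training so every negative
contributes to the loss. The remaining positives (≈ 82% per model) are split
into n validation sets for early stopping. The n models' binarized calls
give a per-gene concordance c_j(g) ∈ {0..n}.

For each candidate threshold c\* the observed count C_j of test positives
with concordance exactly c\* is compared with an empirical background:
B = 1000 repetitions of n random classifiers that each mark as many genes as
the corresponding real model, uniformly without replacement within the
scored universe (unlabeled ∪ test_j). Only marks falling inside the test set
affect the statistic, so the implementation draws the per-classifier
hypergeometric count of marks among test positives and places them
uniformly — exactly the marginal law of full-universe marking (the dense
sampler is kept and used as the oracle in the test suite).

Per bin, significance is assessed with a one-sided t statistic of the
observed overlap against the background **spread**:
`t = (C_j − mean(C̄))/sd(C̄)` with B − 1 degrees of freedom. The observed
overlap is a single draw, so referencing it to the standard error of the
background mean (which shrinks as 1/√B) would flag negligible differences
and destroy the calibration of the machinery; with the spread-referenced
statistic, at most ~10% of null folds (random predictions at matched call
counts) emit candidates at FDR 0.05, as the acceptance suite verifies.
Benjamini–Hochberg FDR is applied across the n bins. The inner threshold is
the minimal bin with FDR < 0.05, or the minimal bin whose background mean is
below 0.1 — the latter additionally requires at least one observed test
positive in the bin, and takes the label on ties since a near-empty
background makes the t-test degenerate. A fold with no qualifying bin
contributes an empty candidate set.

Fold candidates are the unlabeled genes with c_j(g) ≥ c\* (bin counting uses
equality, candidate selection uses ≥, both as specified); known positives,
including test_j, are never candidates. The consensus score CS(g) ∈ {0..m}
counts the outer folds selecting g; positives receive no CS; CS = 0 marks
non-candidates.

## Interpretation

Integrated gradients with a midpoint Riemann sum (64 steps by default — the
technique fixes the path, not the resolution) attribute a query gene's score
to node features (zero baseline) and to edge weights (all-ones input,
all-zeros contrast). Completeness `Σ attr = F(x) − F(baseline)` is exact for
linear models and holds within 1e-3 relative on trained MLPs at default
steps; for stacks containing instance normalization the integrand has a
sharp boundary layer near the zero baseline (variance ≈ ε there), so
convergence in steps is slow and completeness is only qualitative — the
tested contract covers graph-free models. Per model, attribution magnitudes
are minmax-scaled to [0, 1] across the full edge set (or node set, where a
node's importance is the sum of its feature-attribution magnitudes) and
averaged over all n·m models; the query gene's own feature attributions keep
their sign and are scaled by the maximum magnitude across its p features,
giving values in [−1, 1]. A degenerate zero-range minmax maps to 0.

## External validation statistics

Membership gene sets (knockout-phenotype orthologs, differentially
expressed genes, drug targets, druggable genes) are tested with two-sided
Fisher's exact tests; the effect size is the cross-product odds ratio with
Haldane 0.5 correction on zero cells (flagged). Per consensus-score bin k,
the test set is {CS ≥ k} and the comparison is non-positive genes with
CS < k, cumulative at every bin (at the top bin the cumulative and exact
readings coincide); known positives are excluded from test set and
background; BH-FDR runs across bins. Constraint-score comparisons
(LoF/missense intolerance Z) use Tukey's honestly significant difference
(statsmodels; the studentized-range closed form is the independent oracle in
the tests). Drug-targeting degree uses pairwise two-sided rank-sum tests on
genes with ≥ 1 interaction, reporting the median fold change (xDC).
Validation-rate comparisons use a pooled two-proportion z-test. The Dr−
analysis removes known drug targets from the test set and background before
testing druggable-gene enrichment.

## Synthetic benchmark

The generator plants a standard-normal latent coreness per gene and derives
everything from it. Networks are Erdős–Rényi or preferential-attachment
(included because real molecular networks are heavy-tailed) with configured
mean degree, undirected PPI-like and directed GRN-like. Informative features
are `effect_size · coreness + N(0, 1)` (at effect size 2 the
feature–coreness correlation is 2/√5 ≈ 0.894), noise features pure N(0, 1).
The top `core_fraction` of coreness are true cores; each core is labeled
independently with probability `logistic(slope · (coreness − threshold))` —
a logistic ramp is the simplest one-knob realization of a labeling frequency
that rises toward the extreme of the positive distribution (the
selected-at-random-with-probabilistic-gap regime); slope 0 gives uniform 0.5
labeling, large slopes a sharp cut. Non-cores are never labeled. A
validation gene set joins cores and non-cores at rates chosen so the
expected membership odds ratio equals `validation_or` (base rate 0.1).
Identical config and seed give byte-identical outputs.

What the generator does **not** emulate: tissue-specific co-expression
structure, SNP-level association signals, degree–coreness coupling, or
annotation biases of curated databases. Passing the recovery benchmark
therefore shows the machinery is sound end to end — labels leaking only
through features and the planted odds ratio being recovered through the full
train/threshold/consensus path — not that real disease gene sets would
validate at any particular rate.

## Problem sizes and defaults

The recovery benchmark runs 2000 genes, 5% cores, effect size 2, labeling
slope 3, an m = 5 × n = 5 MLP ensemble with B = 1000 — chosen as the
smallest configuration at which hidden positives are plentiful enough
(≈ 25–35) for a stable ranking readout. Null calibration uses 200 replicates
of a 10-model fold over 2000 genes with 10 test positives and call counts of
50–150. Ensemble shape (m, n), B, the FDR level and the 0.7 score threshold
are configuration, not constants.

## Known limitations

- Full-batch training only; no mini-batching or neighbor sampling.
- The NumPy engine is CPU-bound; desk-scale graphs (≲ 10⁴ nodes) are the
  target envelope.
- The random-walk embedding trains a small skip-gram at corpus sizes far
  below the 500-epoch/100-walk defaults' original setting; at desk scale,
  shrink `epochs` and `walk_length` accordingly.
- Logistic-regression / random-forest baselines are not built in; any object
  with `params` / `forward` / `scores` can plug into the trainer.
- No positive-class-prior estimation, bagging variants, or score
  calibration.
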