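# Methods

## Problem setting

Given a cohort of samples with gene-expression profiles and class labels
(e.g. tumour vs. normal), the package frames classification transductively:
all samples — labeled and unlabeled — form one graph, and a graph neural
network predicts every node's class from its own features and those of its
graph neighbourhood. The premise is that expression-similar samples tend to
share a label, so propagating information along similarity edges denoises
individual profiles.

## Preprocessing and feature selection

**Cleaning.** Genes whose mean across samples is exactly zero carry no
signal and are removed (`drop_zero_mean_genes`); the operation is idempotent
and order-preserving. Normalization defaults to per-gene z-scoring
(population SD; constant genes map to zero columns); `none` is available for
the count-scale selection stage. Class imbalance can be corrected by seeded
oversampling with replacement. Oversampling the whole dataset before
splitting duplicates minority rows across train/test — a leakage risk — so
the library leaves the choice to the caller: oversample the full matrix to
mirror the original pipeline ordering, or restrict it to training rows.

**Differential filter.** Counts are library-size normalized to CPM (rows
rescaled to 10⁶). For two groups the difference table holds, per gene:
log₂ fold change of pseudocount-stabilized group-mean CPM, log₂ overall mean
CPM, a Welch (unequal-variance) t-test p-value on log₂(CPM + pc), and
Benjamini–Hochberg FDR. The Welch test replaces a negative-binomial
likelihood-ratio test deliberately: on log-scale CPM with several replicates
per group it is well calibrated (the null simulation in the test suite keeps
the p < 0.05 fraction near 0.05), and it keeps the package dependency-light.
Genes with no variance in either group get p = 1. The filter keeps genes
with |log₂ FC| ≥ log₂(fc_threshold) — two-sided, since down-regulation is as
informative as up-regulation — and p < p_threshold (defaults 2.0 and 0.05;
fold change exactly at the threshold is kept, p exactly at the threshold is
not). The pseudocount default is 0.5, the usual choice to keep logs finite
without drowning small counts.

**Exact stage.** Recursive feature elimination with an L2-regularized
logistic regression: each round drops the `step` genes with smallest mean
|coefficient|; ties eliminate the higher column index first, so identical
columns rank in index order and the output is a strict permutation
(rank 1 = last survivor). The number of genes kept is chosen by stratified
k-fold cross-validation (default 10 folds, reduced with a warning if a class
is smaller): for each N, the mean CV accuracy of the same estimator on the
top-N genes; the selected N is the smallest whose mean is within one
standard error of the best — a deliberate parsimony rule, reflecting that a
handful of strong markers typically matches the accuracy of a much longer
list. With multi-class labels the differential filter runs one-vs-rest and
takes the union. If the filter keeps fewer than two genes the exact stage
falls back to the full gene set with a warning.

## Graph construction

Pairwise Euclidean distances are computed on the normalized, selected
feature matrix. The edge threshold τ defaults to the mean distance over
unordered off-diagonal pairs — including the diagonal's zeros would bias τ
downward. An edge exists where d_ij < τ strictly; boundary ties are
excluded. Self-loops are materialized (a_ii = 1) so each node's
neighbourhood includes itself uniformly in the attention softmax. The
construction is translation-invariant and equivariant to node relabelling,
and the edge set grows monotonically with τ. Note that duplicated rows
(e.g. after oversampling) sit at distance 0 and always connect.

## The model

Layer equations are in the README. Design points that were genuinely open:

- **Attention form.** The pairwise attention map is the reference
  single-layer form LeakyReLU(aᵀ[Wh_i ‖ Wh_j]) with slope 0.2.
- **σ after aggregation.** The aggregated embedding passes through a
  softmax over feature dimensions by default (each output dimension in
  (0, 1), summing to 1 per node); `elu` and `sigmoid` are config
  alternatives. For concatenated heads σ applies per head before
  concatenation; for the averaging output layer σ applies after the head
  average.
- **Aggregation uses the neighbour embedding** h_j inside the sum (not the
  centre node's h_i): attending over a neighbourhood only mixes information
  if what is summed varies with j.
- **Gate spaces.** The update gate z and new-information vector n live in
  the attention-output space (width M); the reset gate r lives in the
  layer-input space (width F_in) so that r ⊙ h is well-formed and the gate
  masks the incoming embedding elementwise, exactly its GRU role. When
  F_in ≠ M (the output layer: 64 → C), a learned projection P maps h into
  the gate space before the convex combination; elsewhere the identity is
  used. Gates are bias-free, as is the attention; both can be extended in
  config but default off.
- **Between-layer activation.** ELU by default. Routing intermediate
  outputs through a log-softmax is available (`interlayer="logsoftmax"`)
  but makes optimization markedly slower to leave its initial plateau: on
  the two-cluster benchmark, runs under that routing commonly sit at chance
  validation accuracy for several hundred epochs before learning, whereas
  the ELU default learns within tens of epochs. Both routings preserve all
  structural invariants (receptive field, equivariance, normalization).
- **Initialization.** Glorot-uniform, from a seeded generator; every run is
  a pure function of its seeds.

**Receptive field.** Masked attention contributes exactly zero weight
outside the adjacency support (masked scores are filled with −10³⁰, whose
shifted exponential underflows to exactly 0.0), and every other per-node
operation is row-local. Consequently a 3-layer stack's output at a node is
*bit-identical* under any perturbation of nodes more than 3 hops away — a
property the test suite checks literally, not approximately.

## Training and evaluation

Full-graph forward per epoch; mean NLL over training nodes; hand-written
Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on the flattened parameter vector,
with gradients from reverse-mode autodiff and verified against central
finite differences in the tests. Early stopping counts epochs without
validation-*accuracy* improvement (default patience 100, max 1000 epochs);
at equal accuracy, parameters with lower validation loss replace the
retained best model. A pure loss-based patience never triggers on small
separable problems because validation loss keeps shrinking as confidence
grows. Non-finite loss aborts with a divergence error. Splits are a seeded
shuffle cut 40/40/20 (validation and test rounded, train takes the
remainder). Metrics: accuracy from the confusion-table trace; for binary
tasks, sensitivity (TPR) and specificity (TNR) with a declared positive
class (the disease label by convention).

## Synthetic data

`gen_expression` draws log-normal counts: per-gene baseline log₂ abundance
uniform on [3, 12], Gaussian log₂ noise (SD 1.0 — the typical per-gene
spread of log-scale expression), and each informative gene shifted by
log2_effect in class 1, alternating up/down. Defaults (200 samples, 500
genes, 20 informative, log2_effect 2.0) give a cohort where the
differential filter should recover essentially all planted genes. What the
generator does *not* emulate: count overdispersion (no negative-binomial
tail), gene–gene correlation, batch effects, or library-size variation
beyond what CPM removes — so passing tests demonstrate the pipeline's
statistical machinery, not robustness to real TCGA artefacts.

`gen_two_cluster_graph` places two unit-SD Gaussian blobs `separation`
apart (default 4 SD in 8 dimensions, at which a nearest-centroid oracle
exceeds 95% accuracy) and builds the adjacency with the mean-distance
threshold. Because that threshold scales with separation, a few
between-class edges persist even at 6 SD (~90% of edges are within-class;
≥95% from about 8 SD).

`fixture_path_graph` is a chain with self-loops and seeded unit features —
the canonical fixture for receptive-field demonstrations.

## Problem sizes and numerical choices

The test suite and acceptance script run at deliberately small scale: oracle
equivalence on graphs of ≤ 8 nodes (20 instances), the benchmark at 300
nodes with 5 seeds, 300-epoch budget and patience 30, feature selection at
200 × 500 with RFE over the filtered set. Attention softmax and log-softmax
are stabilized by row-max subtraction; the unstabilized brute-force versions
agree to 1e−10 in tests. Comparisons between the vectorised model and the
loop-based reference use 1e−6 tolerances (both are float64; differences are
pure summation-order effects).

## Known limitations

- Transductive only: adding a node means rebuilding the graph and
  re-running; there is no inductive inference path.
- Full dense N×N attention: memory and time are quadratic in cohort size;
  fine for hundreds-to-thousands of samples, not for 10⁵ nodes.
- The differential filter assumes approximately log-scale-Gaussian
  expression; heavy overdispersion or zero inflation (single-cell dropout)
  calls for a count-model test instead.
- The mean-distance edge threshold is a heuristic; no attempt is made to
  learn it.
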