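# Methods

This note documents the models, simulators and design decisions behind
`spred` — a simulation-supervised approach to gene regulatory network (GRN)
inference from bulk expression data — in enough detail to reproduce or audit
every computation the package performs.

## Problem setting

Given an expression matrix whose rows are nTF candidate transcription
factors (TFs) plus one target gene and whose m columns are biological
conditions, the task is to decide which TFs regulate the gene.  Instead of
fitting a per-gene expression model and reading off feature importances, a
neural network is trained to predict the edge labels directly.  Reliable
training labels do not exist for real GRNs, so the training set is
synthetic: many random (GRN, expression matrix) pairs produced by a
biophysics-style simulator, with the GRN providing the ground-truth edges.

## Synthetic GRNs

Networks have a strict three-layer structure: nMR master regulators (MRs)
→ nTF TFs → nG target genes.  The MR layer exists to induce co-expression
among TFs — the main confounder in real data — in a controllable way: fewer
MRs (or more MR parents per TF) means more strongly correlated TFs and a
harder inference problem.  Each TF has exactly dMR→TF MR parents and each
gene an in-degree drawn uniformly from an interval [lo, hi] of dTF→G
values; parent sets are uniform without replacement (no bias is assumed
beyond the degree constraints).  Node identifiers are contiguous 0-based
integers in MR, TF, gene block order, which fixes the row ordering of every
matrix downstream.

Each edge carries a signed interaction strength K with |K| ~ Uniform[1, 5],
negated (repression) with probability 0.2, and a Hill coefficient equal to
2 with probability 0.9 and 1 otherwise — the same distribution for both
layers of edges (the layer-specific behavior is not otherwise specified, so
one distribution is applied throughout).  Networks serialize to a
SERGIO-compatible "targets" CSV (child id, regulator count, regulator ids,
K values, Hill coefficients) and a "master regulators" CSV (MR id followed
by one production rate per cell type); both round-trip exactly.

## Expression simulator

Conditions are "cell types": each is a vector of MR production rates.  One
(low, high) rate-range pair is chosen per GRN from a pool of three
defaults — ([0.2, 0.5], [0.7, 1.0]), ([0.5, 1.0], [1.5, 2.5]),
([1.0, 1.5], [2.0, 3.0]) — and each rate is drawn uniformly from the low or
high interval by a fair coin flip per (MR, cell type).  The pool values are
package defaults chosen to span weak-to-strong induction around rate/decay
levels of order one; they are configurable and recorded in run metadata.
100 cell types are simulated per GRN with one cell each, and benchmarks
with m < 100 conditions subsample columns uniformly.

Dynamics follow Hill-regulation ODEs with chemical-Langevin noise,
integrated by Euler–Maruyama:

    dx_i = (P_i(x) − γ·x_i)·dt + η·sqrt(max(P_i, 0) + γ·x_i)·sqrt(dt)·ξ

with shared degradation rate γ (`decay`, default 0.8), noise amplitude η
(`noise_scale`, default 1.0, giving Poisson-like variance at steady state),
ξ standard normal, and x clipped at zero.  For an MR, P_i is its
condition-specific rate; for any other node P_i = Σ_p |K_p|·H_p(x_p) over
parents, with the activating Hill function x^n/(h^n + x^n) for K > 0 and
the repressing form h^n/(h^n + x^n) for K < 0.  The half-response h of each
parent is estimated once per GRN from a deterministic pre-pass: the
noise-free fixed point is analytic layer by layer on the three-layer DAG
(MR level = rate/γ), and h is the parent's mean fixed-point expression over
cell types.  A parent that is identically zero gets a tiny floor (1e-12) to
keep the Hill ratio defined.

Integration uses dt = 0.01, a 2000-step burn-in and 500 further steps
(total time 25, i.e. 20 degradation timescales), starting from x = 0; the
final state is the read-out.  With η = 0 the trajectory converges to the
deterministic fixed point (verified against an independent root solver in
the tests), so the stochastic read-out is a draw from the model's
steady-state distribution.  A warning is emitted if the configured step
count cannot have damped the deterministic transient below 1e-3 (the
transient decays as exp(−γ·t)).  Cells are read at a fixed step count
rather than an adaptive convergence criterion so that runs are exactly
reproducible.

Technical dropout — the measurement artifact, distinct from the neural
dropout regularizer — is modeled simplistically: exactly
round(fraction·entries) entries chosen uniformly without replacement are
set to zero.

What the generator does *not* emulate: library-size variation, outlier
genes, UMI-sampling noise, cascade (TF→TF) regulation and
trajectory/differentiation structure.  Passing benchmarks therefore speak
to the statistical method under the stated generative assumptions, not to
single-cell data or deeply cascaded networks.

## Featurization

Per gene, each expression row is Box-Cox transformed with a per-row
maximum-likelihood λ (searched on [−5, 5]) and then z-scored to mean 0,
SD 1.  If the matrix contains any value ≤ 0 (dropout produces zeros), all
entries are first shifted by the single constant 1 − min(values); the shift
is matrix-wide, not per-row.  Constant rows cannot be scaled to unit
variance; they are set to zero and flagged.

For a context of the nTF TFs plus one target gene (N = nTF + 1 rows), five
symmetric N×N matrices are computed: sample covariance Σ (m − 1
denominator), Pearson and Spearman correlation, discrete mutual information
and the precision matrix (Σ + ε·I)^(−1) with ε = 1e-3.  Mutual information
uses equal-frequency binning with B = max(2, floor(√m)) bins per row and
the plug-in estimator in nats; √m balances bias and variance at the small m
(10–100) this package targets, and the binning is per-row, so TF–TF entries
do not depend on which gene completes the context.  That independence is
exploited for speed: the four moment/rank/MI matrices are computed once per
GRN over all TF and gene rows and sliced per gene, while the precision
matrix is a per-gene (nTF+1)×(nTF+1) inverse.  The fast path is asserted
equal to the direct per-context computation in the tests.

Feature columns are ordered (cov, pearson, spearman, mi, precision) and any
subset can be emitted (ablation hook).  Two sample layouts exist:

* single-pair (SP): for TF i vs gene g, an (nTF + 1) × 5 matrix — the pairs
  (i, j) for every TF j in index order (the self pair (i, i) included:
  variance, 1, 1, self-information, precision diagonal) followed by the
  (i, g) row; label = "i regulates g".  nTF·nG samples per GRN.
* multi-label (ML): for gene g, an (nTF² + nTF) × 5 matrix — all ordered
  TF–TF pairs row-major (symmetric duplicates stored, matching the tensor
  shape the network consumes) then the nTF TF–gene rows; the label is the
  nTF-vector of edge indicators.  nG samples per GRN.

## Models

Both models are small 1-D CNNs over the pair-feature rows.  Because the
rows are an unordered set of pairs, convolution across rows would be
meaningless; the "convolutions" are kernel-size-1 channel mixers (a shared
linear map over the 5 feature channels of each row).

* SPREd-SP: the TF–TF rows and the single TF–gene row pass through
  *separate* stacks of two conv-batchnorm-ReLU blocks (5→16, 16→1
  channels); the concatenated (nTF + 1)-vector feeds a 128-unit ReLU layer
  and a single output logit.
* SPREd-ML: the TF–TF block and TF–gene block each pass through their own
  shared conv(5→1)+ReLU kernel, giving maps of lengths nTF² and nTF; both
  maps are fully connected to nTF output logits, with dropout rate 0.3 on
  the connections from the TF–gene map (training mode only).  The map-to-
  output connection is a single dense layer; hidden widths are
  configurable.

Scores are logistic transforms of the logits.  Batch normalization uses
batch statistics in training and running statistics in evaluation, so
inference is deterministic and batch-independent.  Parameters initialize
with uniform fan-in scaling from a seeded generator.  The engine is a
compact numpy implementation with hand-derived backpropagation, verified
against central finite differences in the test suite.

## Training

Adam (β = 0.9/0.999) with learning rate 2e-4 and L2 weight decay 5e-4
added to the gradient, binary cross-entropy with logits with a
positive-class weight of 9 (positives are 3–7 of 100 candidates in the
default configuration), shuffled mini-batches of 32, and at most 300
epochs.  The loss is computed in log-sum-exp form and is exact for extreme
logits.  By default 10% of the training GRNs are held out — whole GRNs,
never individual samples, so validation genes are never seen in training —
for early stopping (patience 10) with the best-validation checkpoint
restored; `val_fraction=0` recovers the plain fixed-epoch regime.  All
randomness (shuffling, splits, initialization) flows from explicit seeds.

## Evaluation

All metrics are per target gene — ranking the nTF candidates against the
gene's true regulators — and averaged over genes.  Average precision is
AP = Σ_n (R_n − R_{n−1})·P_n over distinct descending score thresholds,
with tied scores grouped at a single threshold; it is preferred over AUPRC
because with very few positives (often one) interpolation artifacts make
AUPRC misleading.  AUROC is the Mann–Whitney statistic with ties counted
one half.  Both are verified against exhaustive brute-force oracles.
Genes with no positive (possible only with external gold standards) are
excluded from averages and counted.  The expected AP of a random ranking
with d positives among nTF candidates is estimated by permutation Monte
Carlo (for d = 1 it is H(nTF)/nTF exactly, ≈ 0.052 at nTF = 100).

The benchmark harness generates seeded test GRNs for a configuration
(numbers of MRs/TFs/genes, degree ranges, m, dropout fraction — each of
which may be a list cycled in equal numbers for heterogeneous benchmarks),
scores them with a trained model, and emits a tidy per-gene table.
External tools' predictions are accepted as (tf_id, gene_id, score) TSVs
aligned by identifier, with missing pairs ranked last.

## Benchmark scale

The package's default experiment shapes mirror the reference configuration
(nMR = 5, dMR→TF = 3, nTF = 100, dTF→G ∈ [3, 7], 250 training and 50 test
GRNs of 100 genes).  The bundled acceptance script and test suite run a
scaled-down version of the same design — nTF = 20, nG = 30, 40 training
GRNs, 10 test GRNs, m ∈ {10, 50}, up to 100 epochs — chosen so the whole
study runs in minutes on one CPU core while preserving the qualitative
structure (sparse positives, TF co-expression through a 5-MR layer, the
m and dropout trends).  Scaled absolute AP values are higher than at
nTF = 100 because the candidate pool is 5× smaller; trend directions, not
absolute values, are the comparable quantities at this scale.  Trend
assertions are made per test GRN (paired across conditions) with a sign
test across the 10 GRNs.

The capacity (memorization) check trains SPREd-SP on 200 random-feature,
random-label samples to loss < 0.05; it uses learning rate 1e-2 without
weight decay, since the production recipe's 2e-4 is deliberately
conservative and the point of the check is representational capacity, not
the training schedule.

## Known limitations

* The simulator is a documented Langevin scheme, not a bit-level clone of
  any external package; absolute expression scales and noise spectra will
  differ from other simulators even at matched parameters.
* Half-responses estimated from noise-free fixed points understate
  effective saturation when noise is large.
* The ML model's hidden architecture between the feature maps and output
  is a single dense layer; deeper variants are configurable but untested.
* Training assumes the candidate TF count at test time equals the training
  nTF; models are not size-generalizing across nTF.
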