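# Methods

## Problem and labeling

The package predicts, for every residue of a protein, a propensity in
[0, 1] for intrinsic disorder and for six disordered functions:
protein binding, DNA binding, RNA binding, ion binding, lipid binding and
flexible linker. Ground truth arrives as DisProt-style region tables
(protein id, label, 1-based inclusive start/end) and is rasterized into an
L×7 binary matrix with the fixed column order
`[disorder, protein_binding, dna_binding, rna_binding, ion_binding,
lipid_binding, linker]`. Residues not covered by any region of a label are
treated as negatives for that label; an optional per-residue mask can
exclude residues from the loss and metrics, but the default is
all-observed. Coordinates are converted once to 0-based half-open
internally; everything user-facing is 1-based. Proteins longer than 30,000
residues are rejected rather than windowed.

## Functional-correlation statistic

The coupling between two function labels X and Y is the reduction in
entropy achieved by predicting them jointly rather than separately,

    IG(X, Y) = H(X) + H(Y) − H(X, Y)   [bits],

i.e. their mutual information, estimated from pooled per-residue
frequencies over all training proteins (the pooling unit is the residue,
matching the residue-level loss; the disorder column is excluded). The
convention 0·log 0 = 0 applies and values are clipped at 0 to absorb
rounding. The matrix is symmetric; its diagonal stores the per-label
entropy H(X). For binary labels the bound 0 ≤ IG ≤ min(H(X), H(Y)) is
enforced as an invariant; perfectly co-occurring fair-coin labels attain
IG = 1 exactly, so no strict upper bound below min-entropy is imposed.

## Architecture

Per protein of length L with embedding width D:

1. **Bi-GRU context encoder.** Forward and backward GRU passes over the
   residue embeddings are concatenated into contextual encodings
   `P ∈ R^{L×2H_b}`.
2. **Attention GRU.** A unidirectional GRU with zero initial hidden state;
   at step i the attention scores are `s_ij = h_{i−1}^T W_a p_j`, weights
   are their softmax over all j (global, not causal), the context is
   `c_i = Σ_j α_ij p_j`, and `h_i = GRU(h_{i−1}, c_i)`. Note the hidden
   state receives residue-specific information only through the attended
   context; per-residue alignment therefore has to be learned through the
   recurrent dynamics, which is the main optimization difficulty of the
   architecture (see "Numerical choices").
3. **Feature mapping.** Six independent linear+ReLU layers map `h_i` to
   function node features `X_i^{(n)} ∈ R^F`.
4. **Graph interaction unit.** A fully connected 6-node graph per residue.
   The 6×6 adjacency A is trainable; off-diagonals are initialized with the
   training-set IG matrix and the diagonal with a self-loop constant of 1.0
   so each node retains its own signal. A is not constrained to stay
   symmetric or non-negative during training. One GCN step per residue with
   a per-target-node kernel:
   `Y^{(n)} = ReLU(Σ_m A_{nm} X^{(m)} W′^{(n)} + b′^{(n)})`. The index
   convention (target node n aggregates from every node m, including the
   self-loop) treats the graph as a standard 6-node GCN applied
   independently at each residue.
5. **Disorder pooling.** `Y^IDR` is the elementwise maximum over the six
   aggregated node vectors.
6. **Heads.** Seven linear+sigmoid heads: disorder reads `Y^IDR`, function
   n reads `Y^{(n)}` (each head consumes only its own node's features).

The sequence-only ablation removes steps 4–5: heads read the mapped
features `X^{(n)}` directly and the disorder head reads their max-pool.
It supports paired graph-vs-sequence comparisons under one training run.

## Training

The loss is the mean over the seven heads of the per-head binary
cross-entropy, each averaged over unmasked residues (natural log; uniform
head weights by default, configurable). Internally the loss is computed on
logits in the numerically stable softplus form; the public
`joint_bce_loss` works on probabilities clipped to [1e−7, 1−1e−7].
Proteins are batched by padding with an all-masked tail; masked residues
are frozen in the recurrences and excluded from the loss.

Optimization is Adam (lr 1e−3 default) with a cosine learning-rate decay
and global gradient-norm clipping at 5.0; recurrent kernels are
initialized orthogonally and input kernels Glorot-uniform. Model selection
returns the parameters with minimum validation loss (the history records
an epoch-0 entry for the untrained model, so loss-reduction curves have an
explicit baseline). Per-head decision thresholds are calibrated on the
validation set by maximizing F1 over the observed scores, ties resolved
toward the larger threshold; a head with a single class defaults to 0.5
with a warning. Binarization uses score ≥ threshold everywhere. Training
is bit-reproducible given the two seeds (parameter init and data order).

## Attribution (LRP)

Layer-wise relevance propagation uses the αβ-rule with α − β = 1
(defaults α=1, β=0; α=2, β=1 available). The relevance seed is the head's
pre-sigmoid logit — the standard choice that keeps the conservation
property meaningful. Positive and negative contributions are separated by
the sign of w·h (equal to the sign of the weight for the post-ReLU inputs
encountered here), and denominators receive a sign-matched 1e−9
stabilizer. Propagation runs through the output head and the GCN layer and
stops at the six mapped node features: the quantity being explained is the
contribution of the functional correlations, not of the recurrent encoder.
For the disorder head, max-pool relevance is routed to the per-dimension
winning node. A node's contribution is the sum of its feature relevances;
an edge's contribution is the sum of its two nodes'. Dataset-level
importance sums the maps over true-positive residues per head. With β=0
and zero biases total relevance is conserved through every propagated
layer, except that an output unit with no positive contribution passes
none on (the documented behaviour of the pure-positive rule).

## Metrics

AUC is the Mann–Whitney statistic (ties counted ½, via scikit-learn, with
a fast midrank implementation inside the bootstrap); AUPR is the
trapezoidal area under the precision–recall curve; APS is the step-wise
average precision; Fmax is the maximum F1 over thresholds drawn from the
observed scores (ties toward the larger threshold). MCC maps degenerate
denominators to 0; BACC is the mean of TPR and TNR, a missing class
contributing rate 0. Dataset-level reports pool residues across proteins
per head; per-protein mode computes metrics within each protein and
averages over proteins where the head has both classes.

Multifunctional residues are grouped by their exact set of ≥2 true
function labels. A residue of a type is counted correct only when every
involved head crosses its threshold; the threshold-free type score is the
minimum of the involved heads' propensities — the conservative choice
consistent with the all-functions-correct rule.

Predictor comparison uses a paired bootstrap with the protein as the
resample unit (default 1000 resamples, seeded) and a two-sided p-value on
the per-head AUC difference; resamples where a head has a single class are
discarded. The bootstrap was preferred over analytic AUC variance
estimates for its generality across all reported metrics.

## Synthetic data

The generator emulates the statistical structure the model exploits, not
real proteomes: uniform amino-acid composition (sequence content
deliberately carries no signal), geometric region lengths (memoryless),
per-label region densities, a symmetric co-occurrence matrix giving the
probability that a placed region of one function spawns an overlapping
region of another (which controls the induced IG), disorder as the union
of all functional regions plus disorder-only segments (functions annotate
disordered residues only), and embeddings equal to the sum of orthonormal
per-label signature vectors over a residue's active labels plus Gaussian
noise of scale 1/SNR. Defaults: 20 proteins, lengths 40–80, per-label
density 0.12, mean region length 8, co-occurrence 0, disorder-only density
0.10, D=32, SNR 5 — small enough for CPU test runs while leaving every
label with enough positives to train and evaluate. What passing tests on
this generator show is that the implementation learns and measures what it
claims on data with a known recoverable structure; they say nothing about
accuracy on real proteins with real PLM embeddings, where signal is
nonlinear, label noise exists, and composition matters.

A `duplicate_labels` option copies one function's regions onto another,
creating a perfectly correlated pair used to verify that training exploits
label correlation (predicted columns of the pair correlate on held-out
proteins).

## Numerical choices and problem sizes

* Softmax rows are stabilized by subtracting the row maximum; padded
  positions get −1e9 before normalization and exact zero weight after.
* Entropy accepts probability vectors summing to 1 within 1e−9; joint
  tables are clipped into [0, 1] to absorb float accumulation.
* Max-pool gradients and LRP pool routing break ties toward the
  lowest-index node.
* Checkpoints are single `.npz` files holding parameters, configs,
  thresholds and the IG matrix used at initialization; save→load→forward
  is bit-exact.
* The training-sanity configuration used by the acceptance checks is a
  20-protein set (lengths 40–80, D=16) with hidden sizes 16/32, F=48,
  Adam lr 2e−2 (cosine), batch 10, 200 epochs — chosen as the smallest
  setup that reliably overfits its training set to AUC > 0.95 on every
  head on one CPU in a couple of minutes. The disorder head converges
  slowest: max-pooling passes gradient only to per-dimension winning
  nodes, and fitting negatives requires all six nodes to be small
  jointly.
* Default model dimensions for real embeddings (D=1024, hidden 128/128,
  F=32) are explicit package choices, configurable in `ModelConfig`.

## Known limitations

* The attention GRU follows the global-context recurrence exactly; it has
  no direct path from residue i's own encoding to h_i, so per-residue
  alignment must be learned, which needs the learning-rate/initialization
  choices above at desk scale.
* LRP does not propagate through the Bi-GRU/attention recurrences, by
  design.
* The generator's independence of sequence content means sequence-only
  baselines cannot be probed with it.
* PSSM features are accepted only as precomputed per-protein matrices;
  no homology search is performed.
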