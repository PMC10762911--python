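# disograph

Joint per-residue prediction of protein **intrinsic disorder** and six
**disordered functions** — protein-, DNA-, RNA-, ion-, lipid-binding and
flexible linker — from per-residue embeddings, with an
information-gain-initialized functional-correlation graph, layer-wise
relevance propagation (LRP) attribution, and a CAID-style evaluation
battery.

## Who this is for

Researchers studying intrinsically disordered regions (IDRs) who want a
single model that emits seven per-residue propensity profiles and exposes
*why* a residue was called functional, via the learned correlations among
functions. The package is fully testable at desk scale: a built-in
synthetic-data generator produces sequences, correlated functional region
annotations, and embeddings carrying a recoverable signal, so every stage
runs without external downloads, GPUs, or pre-trained encoders. Real
protein-language-model embeddings (e.g. 1024-dim ProtT5 vectors) plug in
through the same file interface.

## The model

Residue embeddings `r_1..r_L` pass through

1. a **Bi-GRU**: `P = BiGRU(r_1, …, r_L)` — contextual encodings `p_j`;
2. an **attention GRU**: `s_ij = h_{i-1}^T W_a p_j`,
   `α_ij = softmax_j(s_ij)`, `c_i = Σ_j α_ij p_j`, `h_i = GRU(h_{i-1}, c_i)`;
3. six **feature-mapping layers**: `X_i^(n) = ReLU(h_i W^(n) + b^(n))`;
4. a fully connected six-node **functional graph** per residue, whose
   trainable adjacency `A` is initialized from the pairwise information
   gain `IG(X,Y) = H(X) + H(Y) − H(X,Y)` (bits, estimated on the training
   set) with unit self-loops, aggregated by a GCN:
   `Y_i^(n) = ReLU(Σ_m A_nm X_i^(m) W′^(n) + b′^(n))`;
5. global max-pooling for the disorder feature
   `Y_i^IDR = max_n Y_i^(n)` (elementwise over the F feature dims);
6. seven sigmoid heads: disorder from `Y^IDR`, function `n` from `Y^(n)`.

Training minimizes the mean over the seven heads of the per-residue binary
cross-entropy, selects the parameters with minimum validation loss, and
calibrates one max-F1 decision threshold per head. A sequence-only
ablation (no graph unit) is available for paired comparisons.

LRP with the αβ-rule (default α=1, β=0) propagates each head's pre-sigmoid
logit back through the head and the GCN onto the six node features; a
node's contribution is the sum of its feature relevances and an edge's
contribution is the sum of its two nodes'.

Metrics: AUC (Mann–Whitney, ties ½), AUPR (trapezoidal), APS, Fmax, MCC,
BACC, per-protein aggregation, paired-bootstrap AUC comparison, and joint
evaluation of multifunctional residues (a residue with ≥2 functions is
correct only if *every* function is predicted).

## Worked example

```sh
cat > sim.cfg <<EOF
seed = 29
n_proteins = 8
embed_dim = 12
length_range = 20,35
cooccurrence.protein_binding.lipid_binding = 0.8
EOF
disograph simulate --config sim.cfg --out data
disograph ig --fasta data/proteins.fasta --regions data/regions.tsv --out ig.tsv
cut -f1,5 ig.tsv | head -2
```

```
protein_binding lipid_binding
0.526053273954552       0.038200221215541674
```

The first data row is the `protein_binding` row of the IG matrix: its
entropy H is ~0.53 bits (diagonal) and its information gain with
`lipid_binding` is ~0.038 bits — the coupling injected by the
`cooccurrence` setting — roughly four times the IG of the uncoupled pairs
(~0.01 bits) on this small sample.

```sh
cat > train.cfg <<EOF
seed = 29
max_epochs = 40
batch_size = 6
learning_rate = 0.01
bigru_hidden = 8
attn_gru_hidden = 8
node_feature_dim = 6
val_fraction = 0.25
EOF
disograph train --fasta data/proteins.fasta --regions data/regions.tsv \
    --embeddings data/embeddings.h5 --config train.cfg --out model
disograph predict --checkpoint model/checkpoint.npz --fasta data/proteins.fasta \
    --embeddings data/embeddings.h5 --out preds
disograph evaluate --pred preds --fasta data/proteins.fasta \
    --regions data/regions.tsv
```

```
head    auc     aupr    aps     fmax    mcc     bacc    threshold
disorder        0.7959  0.8747  0.8741  0.8455  0.4663  0.6720  0.6890
protein_binding 0.5848  0.1414  0.1750  0.3143  0.2240  0.6723  0.2567
...
```

This deliberately tiny demonstration (8 proteins of 20–35 residues, 40
epochs, validation-selected epoch 8) leaves most heads barely above
chance — the training-sanity configuration used by the acceptance script
(20 proteins, 200 epochs, larger hidden sizes) reaches AUC > 0.95 on
every head. `disograph explain` prints the node/edge contribution table
for one residue and head, and `disograph compare` bootstrap-tests the
per-head AUC gap of two predictors.

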