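# Methods

`hypermir` scores unobserved miRNA–disease pairs by neural matrix completion
over embeddings learned from two hypergraph views of each entity type. This
note documents the model, its assumptions, the tunable parameters, the
synthetic worlds used for validation, and the numerical choices made where
the design was genuinely open.

## Model

### Similarity layer

Four similarity notions feed the network:

- **Disease semantic similarity (DSS).** Diseases sit in a MeSH-style
  descriptor forest given as (disease, tree-number) rows; ancestors are the
  owners of tree-number prefixes. Two per-ancestor contribution models are
  averaged: a *decay* model in which an ancestor at hop distance *n* above a
  disease contributes Δⁿ (Δ = 0.5; when several paths reach the same
  ancestor the maximum, i.e. shortest-path, contribution is kept), and an
  *information-content* model contributing −ln(n_DAGs_containing/n_diseases),
  which rewards specific (rare) ancestors. Pair similarity is the shared
  ancestors' contribution sum normalized by the two diseases' total semantic
  values, so every component lies in [0, 1].
- **miRNA functional similarity (MFS).** Each disease associated with one
  miRNA is matched to its semantically closest disease associated with the
  other; the two best-match sums are divided by the combined set size. MFS
  is *undefined* for a pair unless both miRNAs have at least one associated
  disease (the denominator would otherwise vanish).
- **Gaussian interaction-profile (GIP) kernel.** exp(−γ‖IP(a)−IP(b)‖²) on
  binary association profiles, with bandwidth γ = γ′/mean squared profile
  norm (γ′ = 1). Defined for every pair, so it backstops the other two.
- **Integrated similarities (IM, ID).** The average of the primary notion
  and the GIP kernel where the primary is defined, the GIP kernel alone
  elsewhere. A disease pair counts as "defined" iff both diseases appear in
  the descriptor table, mirroring the MFS rule; the logarithm in the
  information-content model is natural (the base cancels in the similarity
  ratio and only affects reported raw contributions).

### Hypergraph views and encoder

Node features concatenate the association profile with the integrated
similarity row: miRNAs get `[T | IM]` (M×(D+M)), diseases `[Tᵀ | ID]`. Two
hypergraphs per entity type supply complementary neighbourhood structure:

- *KNN view:* one hyperedge per vertex — the vertex plus its k nearest
  other vertices by Euclidean distance (square incidence matrix, column
  sums k+1). Including the anchor keeps k meaningful (self-distance zero
  would otherwise consume a slot); distance ties break by ascending index
  for determinism.
- *K-means view:* one hyperedge per cluster of a seeded k-means run
  (scikit-learn, random center initialization, single start, ≤300 Lloyd
  iterations). Rows of the incidence matrix sum to exactly 1.

Hyperedge weights are uniform (identity W): nothing in the method assigns
non-uniform weights. Propagation uses
`P = D_v^{-1/2} H W D_e^{-1} Hᵀ D_v^{-1/2}`; zero vertex degrees are
replaced by ε = 10⁻⁸ before the inverse square root, which leaves connected
inputs bit-identical. The encoder stacks `X → ReLU(P X Θ)` layers without
biases (two layers by default).

### Contrastive objective

For each node, its embedding in one view anchors an InfoNCE loss whose
positive is the same node in the other view and whose 2m̄−1 negatives are
all other nodes in both views. The critic is cosine similarity after a
two-layer projection head (shared between the two views of an entity type,
separate per entity type, so the comparison happens in one space), at
temperature τ. The two anchoring directions are balanced by η (0.5 by
default). Anchors are the final-layer encoder outputs *before* view
gating, since the gate is itself computed from those outputs. Per-anchor
terms are summed by default (a mean reduction is available in the config).

### View gating, fusion, decoding

Each view is pooled over the vertex axis (global average pooling — the
gate must be a per-view scalar) and passed through a d → d/2 → 1
feedforward network (ReLU then sigmoid) to a gate α ∈ (0,1); the gated view
is ReLU(α·Z). Per node, the two gated view vectors are fused by multi-head
scaled dot-product attention: each head projects them to queries/keys/values
of dimension d_f = d/N, forms a 2×2 row-stochastic attention matrix, and
mixes the values; head outputs are averaged, the resulting 2×d_f matrix is
vectorized row-wise and mapped by a single linear layer (with bias) to the
fused embedding. One-layer ReLU decoders then produce factor matrices
X_m, Y_d and the score matrix is T̂ = X_m·Y_dᵀ.

### Objective and optimization

The loss is `L = L_RE + λ·L_CL^m + γ·L_CL^d` with
`L_RE = (1−α)/2·‖P_Ω(T−T̂)‖_F² + α/2·‖P_Ω̄(T−T̂)‖_F²`, where Ω is the set of
observed (1) entries of the *training* matrix: associations masked for
evaluation are zeros there, hence weighted as unobserved — they never leak
through the reconstruction term. Optimization is full-batch Adam at
learning rate β. Training is implemented on the package's own tape-based
reverse-mode differentiation engine over numpy (`hypermir.autodiff`),
verified against central differences end to end; all initialization is
Glorot-uniform from a seeded generator, so runs are bit-reproducible.

## Parameters

| name | meaning | default | origin |
|------|---------|---------|--------|
| k | KNN hyperedge neighbours | 13 | selected value from the upstream hyperparameter sweep |
| c | K-means hyperedges | 9 | same sweep |
| α | unobserved-entry weight in L_RE | 0.11 | same sweep |
| β | Adam learning rate | 10⁻⁴ | same sweep |
| η | contrastive direction balance | 0.5 | symmetric choice |
| λ, γ | contrastive weights | 1 | uniform choice |
| τ | InfoNCE temperature | 0.5 | common default; unstated upstream |
| Δ | semantic decay factor | 0.5 | standard value in the DSS literature |
| γ′ | GIP bandwidth scale | 1 | standard value |
| d (embed_dim) | embedding width | 128 | conventional desk-scale size; unstated upstream |
| n_layers | encoder depth | 2 | ditto |
| N (n_heads) | fusion heads | 4 | ditto |
| epochs | training epochs | 500 | unstated upstream; plateau well before this on desk-scale worlds |

Architecture sizes (τ, d, depth, head count, feedforward widths, decoder
depth) are design choices, not published facts; all are exposed in
`Config`. The decoder uses one linear+ReLU layer per entity type. The
fusion output map is the single linear layer its defining equation shows
(its surrounding prose mentions a two-layer feedforward network; the
equation's form was implemented). With head averaging, the vectorized
fused matrix has length 2·d_f = 2d/N, so the output map is 2d/N → d.

### Ablation switches

`Config.ablation` reproduces the standard component knock-outs:
`gcn_amir` swaps the hypergraph operators for plain symmetrically
normalized similarity graphs D^{-1/2}(S+I)D^{-1/2} (the two views use the
integrated and the GIP similarity, a choice the variant's description
leaves open); `hgcn_amir` sets λ=γ=0; `hgclam_concat` replaces attention
fusion with concatenation; `hgcl_ir` fixes the view gates to 1.

## Evaluation protocol

`make_split` holds out 1/10 of the known associations as an independent
test set; `run_cv` runs repeated k-fold cross-validation (5×5 by default)
over the positives, masking each fold from the training matrix and scoring
it against 10 draws of equally many uniformly sampled negative
(zero-entry) pairs. AUC, AUPR (average-precision form) and F1 are averaged
with equal weight over repeats, folds and draws. F1 needs a binarization
convention for the unbounded reconstruction scores: the default thresholds
raw scores at 0.5, the midpoint of the 0/1 regression targets. (Mapping
scores through the logistic function first, an alternative mode, is
degenerate here: ReLU decoders make every score nonnegative, so
sigmoid(score) ≥ 0.5 for every pair and F1 pins at 2/3 on balanced sets.)
A best-threshold sweep is also available. By default the
association-derived similarities are computed once from the full
cross-validation matrix (the common regime); `leakage_safe=True` recomputes
them per fold from training folds only. Negatives are drawn after the
positive split, per evaluation, excluded from all positives.

Per-fold training seeds, repeat-level fold shuffles and negative draws all
derive deterministically from `Config.seed` via `numpy.random.SeedSequence`
spawn keys, so a report is a pure function of (inputs, config).

## Synthetic worlds

`generate_world(M, D, r, density_target, noise_sd, seed)` plants a
low-rank world: entities fall into r contiguous blocks with one-hot latent
centers plus Gaussian jitter (sd = noise_sd); associations are Bernoulli
with probability sigmoid(10·⟨U_i,V_j⟩ + b), the bias b bisected so the
expected density hits the target; similarity matrices are clipped noisy
cosines of the same latent factors. Deriving the similarities from the
factors that generate T makes the method's core premise — similar entities
share associations — true *by construction*, which is what makes recovery a
fair test; block-structured latents give the K-means view a recoverable
ground truth. A random tree-number forest accompanies each world so the
semantic-similarity path can be exercised.

What the worlds do **not** emulate: the heavy-tailed degree distribution of
curated association databases, the depth and redundancy of the real MeSH
hierarchy, name-matching noise between databases, and any biological
correlation structure beyond low rank. Passing recovery tests therefore
demonstrates correctness of the machinery and sensible inductive behaviour,
not expected performance on HMDD-scale data.

Validation problem sizes were chosen to keep the full battery at desk
scale: recovery and ablation checks use M=60, D=40, r=4, density 0.1,
noise 0.05, with a scaled-down protocol of 2 repeats × 5 folds × 3
negative draws at 300 epochs, over 5 world seeds with a majority-pass
rule; the case-study ranking check uses M=40, D=24 worlds at the default
500 epochs with a 64-dimensional embedding. Under those conditions the
pipeline's cross-validated AUC sits near 0.92–0.94, a shuffled-label null
at ~0.5, and the no-contrastive ablation within ±0.01 of the full model —
the contrastive term's benefit at this scale is within noise, consistent
with the small margins reported for the full-scale ablation.

## Numerical choices and degenerate inputs

- Zero-norm projected embeddings: cosine is defined as 0 (an ε=10⁻¹² guard
  inside the normalization keeps gradients finite).
- Two-way softmaxes in the fusion block subtract a detached per-row max
  before exponentiation.
- An all-zero association matrix makes the GIP bandwidth undefined and
  raises a degenerate-input error rather than silently dividing by zero.
- Similarity matrices read from disk are symmetrized as (S+Sᵀ)/2 with a
  logged warning when asymmetry exceeds 10⁻¹²; asymmetry is never an error.
- A disease pair whose combined semantic value is zero (possible only in
  degenerate tables) scores 0 off-diagonal, 1 on the diagonal.
- Non-finite loss components abort training with an error naming the first
  offending term.
- Early stopping (50-epoch plateau) exists but is off by default so that
  epoch counts — and therefore results — are exactly reproducible.

## Known limitations

- Full-graph training is O((M+D)²) per epoch in memory and time; the
  implementation targets desk-scale problems (M, D ≲ 1000) and provides no
  mini-batching or GPU path.
- Exact identifier matching is assumed between the association list and
  the descriptor table; no synonym resolution is attempted.
- Entities absent from the association list simply do not exist for the
  model; supplying precomputed similarity matrices for them does not add
  rows to the prediction.
- The independent-test protocol trains a single model on the 9/10 pool;
  no ensembling over repeats is performed.
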