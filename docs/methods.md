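# Methods

## Problem and model

`lncpred` treats lncRNA–disease association prediction as bipartite link
prediction on a heterogeneous network. Given a binary association matrix
`A ∈ {0,1}^{N_l×N_d}` and a disease-ontology DAG, the pipeline is:

1. similarity construction (semantic `DS`, functional `LF`, GIP kernels
   `LK`/`DK`, integrated `IL`/`ID`, thresholded `I_net`/`D_net`,
   heterogeneous `G_net`, initial features `X⁽⁰⁾ = [[0,A],[Aᵀ,0]]`);
2. local embeddings by node-adaptive feature smoothing (NAFS) of all
   three networks;
3. structural codes of `I_net` and `D_net` by SDNE autoencoders, stacked
   into the bias matrix `SF`;
4. a Transformer encoder over the smoothed heterogeneous features
   (global view), followed by fusion blocks whose two attention
   sub-layers mix the global, local and structural views;
5. a bilinear sigmoid decoder scoring every (lncRNA, disease) pair.

The trainable parts — the affine map aligning lncRNA and disease local
embeddings, both SDNE autoencoders, both Transformer stages and the
decoder — are optimized jointly by Adam on
`L_m = L_link + L_sdne(lnc) + L_sdne(dis)`, where `L_link` is summed
binary cross-entropy over the sampled pairs.

Key modeling assumptions: associations are binary and symmetric in
evidence (no weights, no direction); one ontology term per disease; a
disease's semantics are fully captured by its ancestor closure with
exponentially decaying contributions; unobserved pairs are treated as
candidate negatives even though some are merely undiscovered positives.

## Semantic similarity details

Within `DAG(d)`, the term of `d` contributes 1 and an ancestor `a`
contributes `γ · max{contribution of children of a inside T(d)}`; the
similarity of two diseases is the sum of their shared-ancestor
contributions normalized by the two total semantic values. `γ = 0.5`
(dimensionless decay per DAG level). Evaluation is memoized in reverse
topological order, so diamonds (multiple parents) are handled exactly;
a brute-force recursive oracle cross-checks this on random DAGs in the
test suite.

## Integration conventions

"Has functional/semantic similarity" is operationalized as: the computed
primary value is positive and both entities had the inputs required to
compute it (nonempty associated-disease sets for `LF`). Only then is the
primary value used; otherwise the GIP kernel entry is substituted.
Diagonals of `IL`/`ID` are forced to 1, so the thresholded networks carry
self-loops for any threshold ≤ 1. Two all-zero interaction profiles have
GIP similarity `exp(0) = 1`; this degenerate but well-defined case is
accepted. An all-zero association matrix is rejected (the GIP bandwidth
would be undefined).

The similarity-network threshold comparator is `≥` (an entry exactly at
the threshold keeps its edge).

## NAFS

The propagation operator is `Ĝ = D̃^(r−1) G̃ D̃^(−r)` over the
self-looped graph; its infinite-power limit has the closed form
`Ĝ^∞_{ij} = D̃_ii^r D̃_jj^{1−r} / ΣD̃` (for a simple binary graph,
`(d_i+1)^r (d_j+1)^{1−r} / (2m+n)`). Per node, each smoothing depth
k ∈ {0..K} is weighted by a softmax over the Euclidean distance between
the k-step-smoothed row and the stationary-limit row (computed with
per-node max subtraction for numerical stability; ties are resolved by
the softmax itself, no argmax is involved). Defaults: K = 7, r-ensemble
{0, 0.1, 0.2, 0.3, 0.4, 0.5} combined by elementwise mean; `concat` /
`max` / single-r (`simple`, using the first listed r) modes are
available. The closed form is applied as-is on disconnected graphs even
though the true power limit then differs.

Two input choices were genuinely open and are package decisions:

* The heterogeneous network is smoothed **as a weighted graph**
  (`G̃ = G_net`, which carries unit diagonals by construction). The
  alternative — binarizing by `entry > 0` — produces a near-complete
  graph, because the GIP fallback makes `IL`/`ID` strictly positive
  almost everywhere, and erases all structure; it remains available via
  `nafs.weighted_gtilde = false`.
* The similarity networks `I_net`/`D_net` are smoothed with their own
  integrated similarity matrices (`IL`, `ID`) as initial features — the
  only inputs with the required shapes `N_l×N_l`, `N_d×N_d`.

## SDNE

Two-layer logistic encoder `N → 64 → 32` with a mirrored decoder.
Losses: masked-Frobenius reconstruction with observed edges over-weighted
by β = 5 (any β > 1 preserves the intent; 5 is the package default),
first-order proximity weighted by α = 1e-6, and
`L_reg = ½(ν₁·Σ‖W_enc‖²_F + ν₂·Σ‖W_dec‖²_F)` with ν₁ = 1e-5, ν₂ = 1e-4
(biases are not penalized). The embedding width is half the hidden width
(n_p = 32). The SDNE losses are *exposed to the joint objective* — there
is no private pretraining phase — so the structure codes co-adapt with
the link loss.

## Transformer stages

Multi-head attention uses standard scaled-dot-product softmax over key
positions within each head. A printed variant that normalizes the
exponentiated logits across heads instead of across keys is implemented
behind `enc.paper_softmax` for comparison; it is not row-stochastic and
is off by default. Feed-forward sub-layers are two LeakyReLU affine maps
(slope 0.01). Residual connections with post-layer-normalization wrap
every sub-layer — without them stacks of depth 10/20 do not train.
Fusion blocks contain two attention sub-layers (self-attention, then
attention over the embedding concatenated with the projected `SF`);
`enc.two_stacks` instead builds two sequential half-depth stacks.
Concatenations are followed by learned projections back to the model
width so head-divisibility holds for large head counts.

No positional encodings are used; every attention/FFN block is
permutation-equivariant, and node identity enters only through the
inputs (verified by a permutation test).

Widths: model width n_h = n_h' = 64, FFN width 128, output width
f = 64. Full-scale depths are L1 = 10 (global), L2 = 20 (fusion) with
8 / 64 heads; the scaled benchmark configuration uses L1 = L2 = 2 and 8
fusion heads.

## Optimization and regularization

* **Stable BCE.** The training loss is computed from logits in softplus
  form; clipping sigmoid outputs at 1e-12 (used only in the
  probability-space scoring API) has zero gradient once saturated and
  can permanently stall a deep stack.
* **Initialization.** Glorot-uniform everywhere, with residual-branch
  output projections (attention output, FFN second layer) and the
  bilinear decoder scaled by 0.1 so every block starts near the identity
  and initial logits are unsaturated. This removes a long warmup plateau
  at the default learning rate.
* **Input denoising dropout** (`input_dropout`, default 0.5): the
  smoothed heterogeneous features contain the raw association entries,
  through which a high-capacity decoder can memorize training cells
  without generalizing; dropping these features during training forces
  reliance on the redundant block/similarity structure.
* **Tail weight averaging** (`swa_fraction`, default 0.4): the returned
  parameters are the mean of the final 40 % of epoch iterates, which
  stabilizes the endpoint under per-epoch negative re-sampling and
  dropout.
* **Deep ensemble** (`n_ensembles`, default 3): independently
  initialized and trained members whose sigmoid score matrices are
  averaged. All member randomness is spawned deterministically from the
  fold seed.
* Adam: lr 1e-3, L2 weight decay 5e-3 added to the gradient, β =
  (0.9, 0.999), full-batch (one step per epoch), 150 epochs at full
  scale. Dropout rate 0.4 on all residual branches during training;
  evaluation passes are deterministic (no dropout).

## Cross-validation protocol

Positives are partitioned into k = 5 random near-equal folds. Per fold,
held-out positives are masked to zero and **all** `A`-derived matrices
(`LF`, `LK`, `DK`, `IL`, `ID`, `I_net`, `D_net`, `G_net`, `X⁽⁰⁾`) are
recomputed from the masked matrix; a guard asserts that no test-positive
cell is nonzero in any pair-indexed derived matrix. `DS` depends only on
the ontology and is shared across folds. Test negatives are drawn from
the zeros of the full matrix at the configured negative:positive ratio
(default 1:1; also 1:5, 1:10 or `random`); training negatives are
re-sampled every epoch from the same pool minus the test negatives (a
flag freezes them per fold). Metrics: AUC (rank statistic), AUPR
(average precision, uninterpolated), and thresholded (0.5) accuracy,
recall, specificity, precision and F1; the report carries per-fold rows,
their arithmetic mean, the full configuration echo and the seed.
Identical configuration and seed reproduce the report bit-for-bit.

Ablation switches mirror the module structure: `remove_T1` replaces the
global encoder by a linear projection; `remove_{lnc,dis}_nafs` pass the
raw integrated similarity instead of its smoothed version;
`remove_{lnc,dis}_sdne` zero the corresponding half of `SF` and drop its
loss term (both together reduce the bias sub-layer to self-attention
over a linear transform of the embedding).

## Synthetic benchmark: what it shows and what it does not

The generator plants `B` latent blocks: entities are assigned round-robin
and `A_ij ~ Bernoulli(p_in)` within blocks, `Bernoulli(p_out)` across
(defaults 60×50, B = 5, p_in = 0.3, p_out = 0.02, an ≈ 7 % density
comparable to curated association tables). The ontology is a random
rooted tree whose per-block subtrees contain that block's diseases, so
semantic similarity correlates with block identity, mimicking the fact
that related diseases share MeSH ancestry.

Because within-block zeros and within-block positives are exchangeable
by construction, a perfect block oracle — and hence any method — is
capped near AUC 0.81–0.83 at these settings (≈ 20 % of positives are
cross-block noise). Reaching ≈ 0.80 therefore demonstrates essentially
complete recovery of the planted structure, and the label-shuffled
control verifies the signal is real. What the benchmark does **not**
emulate: scale-free degree distributions, correlated noise, biased
curation (well-studied diseases have more recorded links), multi-tree
MeSH positions, or truly unknown negatives; passing it shows the
pipeline and its safeguards work, not that real-data headline numbers
transfer.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the scaled configuration
(60×50 benchmark, L1 = L2 = 2, 8 fusion heads, 50 epochs, 5 folds,
3-member ensembles); unit-level end-to-end tests use a 30×24 fixture
with a width-16 encoder. These sizes are the package's reference
conditions for the synthetic study.

## Known limitations

* Full-batch autograd training is CPU-bound and scales roughly with
  `(N_l+N_d)²`; thousands of nodes call for minibatched attention and a
  GPU framework.
* The GIP fallback makes every entity pair "similar" to some degree;
  with very sparse `A` the kernels approach degeneracy (all-zero
  profiles give similarity 1, logged as a design note above).
* Negative sampling treats unknown pairs as negatives; reported
  precision-type metrics are pessimistic to an unknown degree on real
  data.
* The ensemble and weight averaging triple training cost; set
  `n_ensembles = 1` for quick exploration.
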