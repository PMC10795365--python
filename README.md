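# lncpred

Graph-Transformer link prediction for lncRNA–disease association networks.

Long noncoding RNAs (lncRNAs) regulate gene expression, differentiation and
tumorigenesis, and experimentally validating which lncRNAs drive which
diseases is slow and expensive. `lncpred` ranks unobserved lncRNA–disease
pairs from (a) a binary association matrix `A` (N_l × N_d) of validated
pairs and (b) a MeSH-style disease-ontology DAG, so that laboratory effort
can focus on the most promising candidates.

## Model

Three complementary views of the heterogeneous lncRNA–disease network
`G_net = [[IL, A], [Aᵀ, ID]]` are fused end-to-end:

1. **Similarity layer.** Disease semantic similarity `DS` from shared DAG
   ancestors with decay γ = 0.5; lncRNA functional similarity `LF` from
   best-match semantic comparison of associated-disease sets; Gaussian
   interaction-profile (GIP) kernels `LK`, `DK` over rows/columns of `A`
   as fallback where `LF`/`DS` are unavailable, giving integrated
   similarities `IL`, `ID` and thresholded networks `I_net`, `D_net`
   (α = β = 0.6).
2. **Local view (NAFS).** Training-free node-adaptive feature smoothing:
   features are propagated with `Ĝ = D̃^(r−1) G̃ D̃^(−r)` and each node
   weights its smoothing depths 0..K (K = 7) by softmax of the Euclidean
   distance to the closed-form stationary limit `Ĝ^∞`, then the ensemble
   over r ∈ {0, …, 0.5} is averaged.
3. **Structural view (SDNE).** One logistic autoencoder per similarity
   network encodes adjacency rows into codes `M̂`, `D̂`; reconstruction
   (edges over-weighted by β = 5), first-order proximity and L2 terms join
   the global objective. The stacked codes `SF = [M̂; D̂]` act as a
   structural inductive bias.
4. **Global view + fusion (Transformer).** A Transformer encoder embeds
   the NAFS-smoothed heterogeneous features; fusion blocks then apply two
   attention sub-layers each — one over the current embedding, one over
   its concatenation with `SF` — and a bilinear decoder scores each pair:
   `Â(l, d) = σ(x_lᵀ W_B x_d)`.

Everything trains jointly under `L_m = L_link + L_sdne¹ + L_sdne²`
(binary cross-entropy over sampled positive/negative pairs plus both SDNE
losses) with one Adam optimizer (lr 1e-3, weight decay 5e-3). Evaluation
uses leakage-safe k-fold cross-validation: each fold masks its held-out
positives and recomputes every `A`-derived matrix from the masked copy.

## Worked example

```python
from lncpred import SyntheticSpec, generate_synthetic, TrainConfig, run_cv
from lncpred.fusion import EncoderConfig

dataset, ontology = generate_synthetic(SyntheticSpec(seed=1))
cfg = TrainConfig(epochs=50, seed=50, enc=EncoderConfig(l1=2, l2=2, h2=8))
report = run_cv(dataset, ontology, cfg)
for name, value in report.mean.items():
    print(f"{name:12s} {value:.4f}")
```

prints

```
auc          0.8028
aupr         0.7935
f1           0.6346
acc          0.6955
recall       0.5318
specificity  0.8591
precision    0.7908
```

The benchmark plants 5 latent blocks (60 lncRNAs × 50 diseases,
within-block association probability 0.3, cross-block 0.02) and aligns the
disease ontology with the blocks. A mean AUC of 0.80 means held-out links
are recovered almost up to the information ceiling of the design: roughly
a fifth of the planted positives are cross-block noise that no method can
separate from cross-block negatives, which caps the attainable AUC near
0.81–0.83 depending on the fold draw. On label-shuffled data the same
pipeline stays at chance (AUC ≈ 0.5).

## Command line

```bash
lncpred synth --n-lnc 60 --n-dis 50 --blocks 5 --p-in 0.3 --p-out 0.02 --seed 1 --out-dir data/
lncpred similarity --assoc data/associations.tsv --onto data/ontology.tsv --map data/mapping.tsv --out-dir sims/
lncpred cv    --assoc data/associations.tsv --onto data/ontology.tsv --map data/mapping.tsv --config cfg.yaml --out report.json
lncpred train --assoc ... --onto ... --map ... --out model.pkl
lncpred predict --model model.pkl --out scores.tsv --top-k 15
```

`predict` writes per-disease ranked candidate lncRNAs
(`lncrna_id  disease_id  score  rank`), the format used for case-study
style top-k inspection.

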