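# modilm

Multi-omics disease classification from matched molecular profiles
(e.g. miRNA expression, mRNA expression, DNA methylation measured on the
same patients). The package is aimed at computational biologists who want
a tested, configurable implementation of a graph-attention multi-omics
classifier that can be exercised end to end on synthetic data — no
external downloads required.

## The model

Given Q omics views `X^(q) ∈ R^{N×d_q}` with shared samples and integer
class labels `y ∈ {0,…,p−1}`:

1. **Per-view feature filtering** (fit on training samples only): drop
   features with missing/INF entries or more than 10% zeros, apply a
   variance floor, then rank features by their one-way ANOVA F statistic
   against the labels and keep the top J (the printed "keep F < 0.5" rule
   and a "drop F = 0" rule are also available).
2. **Sample-similarity network per view**: cosine similarity
   `S_ij = x_i·x_j / (‖x_i‖‖x_j‖)`; the threshold θ is the (k·N)-th
   largest value of the full ordered-pair similarity multiset (self-pairs
   included), so each node retains on average ≥ k edges. The weighted
   adjacency `A` keeps `S_ij` on surviving edges, and enters the encoder
   as `Ã = D̂^{-1/2}(A + I)D̂^{-1/2}`.
3. **Multi-head graph attention per view**: each of L layers (default 2)
   computes, per head m of M = 8,
   `α_ij = softmax_{j∈N(i)∪{i}} LeakyReLU(aᵀ[W h_i ‖ W h_j])` on the
   support of `Ã`, aggregates `h′_i = Σ_j α_ij W h_j`, concatenates heads,
   and applies LeakyReLU. Layer inputs are pre-smoothed by `Ã` (a
   `pure_gat` switch disables this).
4. **Per-view MLP head**: t = 2 hidden LeakyReLU layers, a linear map to p
   logits and a softmax give a class-probability row `φ^(q)_i` per sample.
   Its loss is a class-frequency-weighted cross-entropy with weights
   `S_ρ = count(ρ)/N` (an `inverse_frequency` switch gives conventional
   reweighting).
5. **Cross-omics tensor fusion (VCDN)**: per sample, the rank-one tensor
   `V_{i,a_1…a_Q} = Π_q φ^(q)_{i,a_q}` (entries sum to 1) is flattened to
   a `p^Q` vector and classified by a one-hidden-layer network with an
   unweighted cross-entropy loss.
6. **Total loss** `L = Σ_q L^(q)_head + γ·L_VCDN` (γ = 1) minimized with
   Adam at learning rate 1e-4, after a per-view pre-training phase.

Training is transductive: unlabeled (e.g. test) samples sit in the graphs
and receive embeddings but never contribute to a loss. New samples can
also be attached at predict time using the stored θ.

The trainable stack runs on a compact numpy reverse-mode autodiff core
(`modilm._autodiff`), gradient-checked against finite differences.

## Worked example

```python
from modilm import SimSpec, MODILMClassifier, generate_dataset, split_dataset
from modilm.experiments import run_synthetic_experiment

# three views, three classes, strong class separation
result = run_synthetic_experiment(SimSpec(n_samples=200, n_classes=3, delta=3.0),
                                  seed=1)
print(result.metrics.to_dict())
print(result.log)
```

prints

```
{'acc': 1.0, 'f1_weighted': 1.0, 'f1_macro': 1.0, 'support': {0: 20, 1: 20, 2: 20}}
{'kept_features': [50, 50, 50], 'theta_per_view': [0.883, 0.894, 0.894],
 'final_joint_loss': 125.4, 'final_pretrain_loss': 0.149}
```

i.e. after filtering each view to its 50 most discriminative features and
building graphs with θ ≈ 0.89, the fused classifier labels all 60 held-out
samples correctly (`support` counts test samples per class). The joint
loss is dominated by the fusion term, which is a sum (not mean) over the
140 training samples.

The same pipeline is available from the shell:

```bash
modilm simulate --out data/ --n 200 --classes 3 --delta 3 --seed 1
modilm fit --config data/config.yaml --model-out model.pkl --seed 1 --k 5
modilm predict --model model.pkl --config data/config.yaml --out preds.tsv
modilm evaluate --predictions preds.tsv --truth data/labels.csv
```

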