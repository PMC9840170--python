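# pathattn

Interpretable cell-type annotation for single-cell RNA-seq, built around a
transformer whose first layer is a knowledge-masked linear embedding from
genes to pathway (or regulon) tokens.

## The problem

Transferring cell-type labels from an annotated reference to a new query
dataset is a core step in single-cell analysis. Deep annotators are fast and
accurate, but their latent spaces are usually untraceable back to biology.
`pathattn` follows a different design: every latent dimension is a *named
gene set*, so the model's internal attention doubles as a biological
read-out, and a query can be embedded, annotated and interpreted in one
pass — without any batch covariates.

## The model

For a cell with expression **e** ∈ ℝⁿ over n genes and a gene-set collection
of k sets, a binary mask **M** ∈ {0,1}ⁿˣᵏ (Mᵢⱼ = 1 iff gene i belongs to set
j) gates a learnable weight tensor **W** ∈ ℝⁿˣᵏˣᵐ:

- masked embedding: **W**′ = **W** ⊙ **M**, token matrix
  **T**ⱼ𝒹 = Σᵢ W′ᵢⱼ𝒹 eᵢ, so token j only receives signal from the member
  genes of set j (m = 48 embedding dimensions by default);
- a learnable class token **CLS** ∈ ℝᵐ is prepended to **T**;
- H-head self-attention: per head,
  **A** = softmax(**QK**ᵀ/√(m/H)), **O** = **AV**, heads concatenated and
  projected, with residual connections and a two-layer feed-forward
  sublayer;
- the CLS row of the block output feeds a fully connected classifier with a
  softmax over cell types; a cell whose highest probability falls below a
  cutoff (default 0.95) is annotated **"Unknown"**, which is how novel cell
  types are discovered;
- the head-averaged attention of CLS over the k pathway tokens is exported
  as the cell's **attention embedding** — an interpretable, batch-insensitive
  k-dimensional representation.

Training is 20 epochs of momentum SGD with cosine learning-rate decay on a
stratified 70/30 train/validation split, cross-entropy loss, and the mask
re-applied after every step so off-mask weights are *exactly* zero at all
times. The model is implemented in NumPy with hand-derived, finite-
difference-checked gradients.

Downstream, the package provides signature-attention ("marker") tests per
cell type (one-vs-rest Wilcoxon rank-sum, Benjamini–Hochberg adjusted),
Louvain sub-clustering in attention space, per-token gene-importance scores
(mean |W′| across embedding dimensions), and dataset-difficulty statistics
(log₁₀ size, number of types, Shannon entropy of the reference label
distribution, and the Kullback–Leibler divergence between reference and
query label proportions, both in bits).

A first-class synthetic-data module generates pathway-driven
negative-binomial counts with known ground truth (driver gene sets per cell
type, log-normal library sizes, optional gene-wise batch factors, optional
held-out cell types), so the whole pipeline is testable end to end without
external downloads.

## Worked example

```python
from pathattn import (
    ModelConfig, TrainingConfig, align_to_vocabulary, attention_embedding,
    build_mask, generate, predict, prepare_model_input, rank_attentions, train,
)
from pathattn.synthetic import SyntheticSpec

# simulate a pathway-driven study: 5 cell types, each driven by one of 20 pathways
data = generate(SyntheticSpec(seed=1))
mask = build_mask(data.truth_gmt, data.reference.gene_names)

reference = prepare_model_input(data.reference)
query = align_to_vocabulary(prepare_model_input(data.query), reference.gene_names)

model, history = train(reference, mask, ModelConfig(seed=1), TrainingConfig(seed=1))
print(f"best validation accuracy: {max(history.val_acc):.3f} (epoch {history.best_epoch})")

result = predict(query, model, cutoff=0.95)
accuracy = (result.predicted == data.query.labels).mean()
print(f"query accuracy: {accuracy:.3f}")
print(f"cells rejected as Unknown: {(result.predicted == 'Unknown').sum()}")

embedding = attention_embedding(query, model)
markers = rank_attentions(embedding, result.predicted)
top = markers[(markers.group == "T2") & (markers.direction == "up")].nsmallest(3, "rank")
print("top attention tokens for T2:", ", ".join(top.token))
```

Output:

```
best validation accuracy: 0.973 (epoch 18)
query accuracy: 0.912
cells rejected as Unknown: 74
top attention tokens for T2: PW_02
```

The model recovers the true labels for the confidently annotated cells
(96% of all query cells are correct when the Unknown cutoff is disabled;
with the 0.95 cutoff on, 74 borderline cells are rejected instead of
guessed, which is counted against accuracy here), and the top-ranked
attention token for type T2 is `PW_02` — exactly the pathway the generator
used to drive that type, so the interpretability read-out points back at
the planted biology.

The same pipeline is available from the shell:

```sh
pathattn simulate --seed 1 --out sim/
pathattn train --ref sim/reference.csv --label-key cell_type \
    --gmt sim/truth.gmt --out model.ckpt --history history.csv
pathattn predict --model model.ckpt --query sim/query.csv \
    --label-key cell_type --out predictions.csv --attn attention.csv
pathattn stats --ref sim/reference.csv --query sim/query.csv --label-key cell_type
pathattn rank-attn --attn attention.csv --groups groups.csv --out markers.csv
pathattn gene-importance --model model.ckpt --token PW_02 --out importance.csv
pathattn subcluster --attn attention.csv --out clusters.csv
```

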