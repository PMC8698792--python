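# embeddti

Drug–target binding-affinity prediction from **two-level molecular graphs**
and **pretrained amino-acid embeddings**.

Identifying which small molecules bind which protein targets, and how
strongly, is a central step in drug discovery and repositioning. This
package treats the problem as a regression task: given a drug's SMILES
string and a target's amino-acid sequence, predict a continuous binding
affinity — pKd = −log₁₀(Kd / 10⁹) for dissociation-constant data (Kd in
nM), or a KIBA-style composite score. It is aimed at computational
chemists and ML practitioners who want an inspectable, pure-Python
implementation of a graph-based affinity predictor, including its
segmentation algorithm, featurization layouts, evaluation metrics, and a
virtual-screening ranking step.

## Model

Three branches are learned jointly and fused:

* **Atom graph branch.** RDKit parses the SMILES into a molecular graph
  (atoms = nodes, bonds = edges). Each atom gets a 101-dimensional binary
  feature vector (element symbol, degree, total/implicit H counts, total
  valence, formal charge, aromaticity, ring membership). A scaled
  dot-product node-attention layer forms H⁽⁰⁾ = αX with
  α = softmax(XW_Q(XW_K)ᵀ/√d_k), followed by three graph-convolution
  layers H⁽ˡ⁺¹⁾ = ReLU(D̃^{-1/2}ÃD̃^{-1/2}H⁽ˡ⁾W⁽ˡ⁾) (Ã = A + I) with
  widths N → N → 2N → 4N, an element-wise max-pool over nodes, and two
  fully connected layers to a 128-d vector.
* **Substructure graph branch.** The molecule is segmented into
  substructures — every bond outside any ring, plus ring clusters formed
  by iteratively merging simple (SSSR) rings that share ≥ 3 atoms — and a
  coarser graph is built with one node per substructure (35-d features:
  atom count, neighbour count, hydrogen count, ring / non-ring-bond
  flags). The same attention + GCN architecture (independent parameters)
  yields a second 128-d vector. A substructure vocabulary (canonical
  fragment SMILES → id) can be built over a compound library.
* **Protein branch.** Amino acids are treated as words: GloVe-style
  embeddings are pretrained from windowed co-occurrence counts over a
  protein corpus, then a three-layer 1-D CNN (1000/256/32 filters, kernels
  8/8/3) over the length-1000 index-encoded sequence, global max-pool and
  two fully connected layers produce a third 128-d vector.

The concatenation T = P ⊕ Am ⊕ Cq ∈ R³⁸⁴ passes through fully connected
layers 384 → 1024 → 512 → 1 (dropout 0.2) to the scalar affinity. Training
minimizes MSE with Adam; evaluation reports MSE, concordance index (ties
in predictions score 0.5), Pearson and Spearman correlations. The network
— attention, GCN, CNN, Adam, backprop — is implemented in NumPy with a
small reverse-mode autodiff engine whose gradients are validated against
finite differences in the test suite.

## Worked example

Train on synthetic data (noise-free toy affinity of simple molecular and
protein descriptors), evaluate on the held-out sixth, and screen:

```python
import numpy as np
import embeddti as e
from embeddti.neural_model import ModelConfig, train_model

records = e.generate_synthetic_dataset(n_drugs=40, n_proteins=20,
                                       n_records=500, noise_sd=0.0, seed=5)
split = e.split_dataset(records, seed=5)
train = [records[i] for i in split.train_indices]
test = [records[i] for i in split.test_indices]

config = ModelConfig.small(epochs=20, batch_size=32, learning_rate=0.003)
state = train_model(train, config, seed=6)

y_true = np.array([r.affinity for r in test])
y_pred = np.array([e.predict(r.drug_smiles, r.protein_sequence, state)
                   for r in test])
print(f"test MSE      {e.mse(y_true, y_pred):.4f}")
print(f"test CI       {e.concordance_index(y_true, y_pred):.3f}")
print(f"test Pearson  {e.pearson(y_true, y_pred):.3f}")
print(f"test Spearman {e.spearman(y_true, y_pred):.3f}")
```

prints (about one minute on one CPU):

```
test MSE      0.0120
test CI       0.963
test Pearson  0.994
test Spearman 0.988
```

A held-out MSE of 0.012 against a label variance of 0.90 means the model
explains essentially all of the (noise-free) signal; a CI of 0.963 means
96.3 % of record pairs with different true affinities are ranked in the
correct order. `ModelConfig()` (no arguments) gives the full published
layer widths; `ModelConfig.small()` shrinks every width for CPU-scale
runs while keeping the architecture.

The same pipeline is available from the shell:

```bash
embeddti make-synthetic --out data.csv --n-records 500 --seed 5
embeddti train --data data.csv --out model.ckpt --config small.yaml --seed 6
embeddti screen --model model.ckpt --smiles mols.txt --target target.fasta \
    --top 10 --out ranked.csv
embeddti evaluate --pred preds.csv
```

plus `pretrain-embeddings` (FASTA corpus → embeddings TSV), `build-vocab`
(SMILES list → substructure-vocabulary TSV) and `predict` (one pair).

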