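# Methods

## Problem setting

Binding affinity between a small-molecule drug and a protein target is
modeled as a continuous regression target. Dissociation constants are
mapped to the log scale, pKd = −log₁₀(Kd/10⁹) with Kd in nanomolar, so a
Kd of 10 µM becomes pKd = 5 and a Kd of 1 nM becomes pKd = 9; composite
KIBA-style scores are used untransformed. Inputs are a SMILES string for
the drug and an amino-acid sequence for the target.

## Molecular representation

**Atom graph.** RDKit performs parsing, sanitization, aromaticity
perception and implicit-hydrogen assignment; atom order is RDKit's parse
order. Each atom is featurized as a 101-bit vector: element symbol
one-hot over a fixed 43-symbol list plus an "other" slot (44), degree
0–10 (11), total H count 0–10 clamped (11), implicit H count (11), total
valence (11), formal charge −5…+5 clamped (11), plus aromatic and
in-ring flags. The slot allocation 44+11+11+11+11+11+1+1 follows the
conventions of comparable atom featurizers; counts above the range clamp
into the last slot. Every row therefore sums to 6, 7 or 8 (six one-hot
groups plus up to two flags).

**Substructure segmentation.** Simple rings are the symmetrized smallest
set of smallest rings (SSSR). Ring clusters are merged pairwise whenever
two (possibly already merged) clusters share at least three atoms, and
the merge is iterated to a fixpoint, which guarantees that no two final
ring substructures share three or more atoms (a single pairwise pass does
not). Every bond outside any ring becomes a two-atom bond substructure.
Any atom left uncovered — a one-atom molecule, or a bare ion in a
multi-fragment SMILES — becomes a degenerate single-atom substructure, so
the substructure graph always has at least one node and covers every
atom; downstream max-pooling requires a non-empty graph. Substructure
identity for the vocabulary is the canonical SMILES of the induced
fragment (broken ring bonds hydrogen-capped), which makes vocabulary
construction deterministic: the same SMILES list always serializes to a
byte-identical TSV.

**Substructure graph.** One node per substructure; two nodes are adjacent
iff their atom sets intersect. The 35-bit node features are atom count
0–10 clamped (11), neighbouring-substructure count (11), total member
hydrogen count (11), and two flags (contains a ring / is a non-ring
bond). "Number of edges connected to the substructure" is interpreted as
the number of neighbouring substructures in this graph.

## Protein representation

Each amino acid is a token: the 20 standard letters plus "X" for anything
else, with PAD = 0. Co-occurrence counts are accumulated over a sliding
window (default 5) with 1/distance weighting, symmetrically, and never
across record boundaries. Embeddings minimize the GloVe weighted
least-squares objective with f(x) = min(1, (x/x_max)^α), α = 0.75,
x_max = 100, via AdaGrad (these weighting constants and the optimizer are
the standard GloVe choices; the corpus-scale pretraining interface
accepts any FASTA). The final embedding is the sum of word and context
vectors; the PAD row is fixed at zero. The default dimensionality is 128,
matching the CNN input width. Sequences are index-encoded to exactly
L = 1000 positions (truncate, then right-pad with PAD).

## Network

Both graph branches apply scaled dot-product attention once, producing
the GCN input H⁽⁰⁾ = αX with α = row-softmax((XW_Q)(XW_K)ᵀ/√d_k),
d_k = 64. Query/key projections only — no value projection — keep the
attended output in the original feature space, which the subsequent GCN
dimensions require; disabling attention (H⁽⁰⁾ = X) is the no-attention
ablation. The two branches use independent parameters. Three GCN layers
follow, H⁽ˡ⁺¹⁾ = ReLU(D̃^{-1/2}ÃD̃^{-1/2}H⁽ˡ⁾W⁽ˡ⁾) with Ã = A + I and
widths N → N → 2N → 4N (N = 101 atoms, 35 substructures); self-loops
exist only inside the normalization, never in the stored adjacency. A
column-wise max over nodes pools to 4N, then FC 4N → 1024 → 128. The
post-pool hidden width mirrors the fusion head's first hidden size, a
choice left open by the published hyperparameter table.

The protein branch is embedding lookup → three ReLU 1-D convolutions
(1000, 256, 32 filters; kernels 8, 8, 3) → global max-pool over positions
→ FC 32 → 1024 → 128. The pooling/flattening step and first FC width are
configurable; global max-pool keeps the branch independent of sequence
length bookkeeping.

Fusion concatenates the three 128-d vectors (384) and regresses through
FC 384 → 1024 → 512 → 1 with dropout 0.2 after each hidden layer
(training only). Training is minibatch Adam (default batch 512, learning
rate 5e-4, 1500 epochs) on MSE; initialization is seeded Glorot-uniform;
when a validation set is supplied the best-validation-MSE snapshot is
retained and used for inference. The whole forward/backward pass runs on
a small reverse-mode autodiff core over float64 NumPy arrays; its
gradients are checked against central finite differences in the tests.

**Attention interpretation.** Per-node importance is the column mean of α
(how much every node attends *to* this node), min–max normalized so the
most-attended node scores 1.0 and the least 0.0; a single-node or
perfectly uniform case maps to all ones.

## Data handling

Triples CSV (drug_id, smiles, protein_id, sequence, affinity) and
matrix-style layouts (compound list, protein list or FASTA, dense
affinity TSV with an "NA" sentinel, optional Kd→pKd transform) are both
supported. Splitting follows the six-part protocol: a seeded shuffle into
six near-equal parts, part 0 held out for testing, the other five serving
as cross-validation folds; the split is at the record (pair) level
(cold-drug / cold-target splits are out of scope).

## Synthetic data

The generator emulates the *shape* of benchmark affinity data without any
download. Drugs are concatenations of 1–5 fragments from a fixed grammar
(short chains, halogenated carbons, carbonyls, benzene/pyridine/
thiophene/cyclohexane/piperidine/naphthalene units), which guarantees
parseable SMILES with at most 40 heavy atoms — the same size cap used for
the published screening library. Proteins are uniform over the 20
standard letters with lengths 50–300 (kinase-domain scale). Labels follow

    affinity = 4.0 + 0.8·(aromatic rings) + 0.5·(heavy atoms)/10
             + 2.0·(hydrophobic fraction) + N(0, noise_sd)

with hydrophobic residues {A,V,L,I,M,F,W,Y} and default noise_sd = 0.3
(≈ typical inter-assay noise on the pKd scale), placing labels in a
realistic 4–10 band. The function is smooth in descriptors every branch
can observe, so learning it end-to-end exercises the whole architecture.
What passing tests on this data do **not** show: performance on real
binding panels, where the structure–affinity map is far from additive,
compounds are larger and more diverse, and sequence–affinity signal is
not a residue-composition effect. The generator validates the machinery,
not the chemistry.

## Problem sizes and numerical choices

Tests and the acceptance script use the reduced-width configuration
(`ModelConfig.small()`: embed 8, filters 8/8/8, branch dim 16, fusion
32/16, protein length 64) — the topology is identical to the full
configuration and all dimension contracts are additionally checked at the
published widths. Memorization uses 10 records × 300 epochs; the
generalization check uses 500 records (5/6 train, 1/6 held out, noise-free
labels) × 20 epochs, where the trained model must beat the mean predictor
(held-out MSE below the label variance; measured ≈ 0.01 vs ≈ 0.9).

Other numerical choices: float64 throughout; softmax is max-shifted for
stability; max-pool gradient routes to the first maximal row on ties;
attention on a single-node graph is exactly the identity; the
normalization D̃^{-1/2}ÃD̃^{-1/2} is always well-defined because every
node gains a self-loop. Checkpoints are single-file NPZ archives holding
a format version, the YAML config, loss traces, and final plus
best-validation parameter tensors.

## Known limitations

* No bond-type, stereochemical or 3-D information (edges are unlabeled by
  design).
* The published table leaves several widths unspecified (drug-branch
  post-pool FC, protein FC, embedding dimension, GloVe hyperparameters);
  the defaults documented above are this package's choices and are all
  configurable.
* Screening-rank direction is a flag (`desc` default: higher predicted
  affinity first) because score-sign conventions differ between data
  scales.
* Pure-NumPy training is CPU-bound and sample-at-a-time; it is meant for
  desk-scale experiments, not for full benchmark-scale training.
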