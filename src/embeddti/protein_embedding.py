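"""Amino-acid embeddings pretrained GloVe-style on a protein corpus.

Each amino acid is treated as a word. Global co-occurrence counts are
accumulated over a sliding window with 1/distance weighting, and dense
embedding vectors are fit by minimizing the GloVe weighted least-squares
objective

    J = sum_ij f(X_ij) (w_i . w~_j + b_i + b~_j - log X_ij)^2,
    f(x) = min(1, (x / x_max)^alpha)

with AdaGrad updates. The final embedding for a token is the sum of its
word and context vectors. The PAD token (index 0) never participates in
training and its embedding row is fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "AminoAcidVocabulary",
    "CooccurrenceMatrix",
    "EmbeddingMatrix",
    "EncodedProtein",
    "read_fasta_sequences",
    "build_cooccurrence",
    "glove_objective",
    "train_glove",
    "encode_protein",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard letters
UNKNOWN_TOKEN = "X"
PAD_TOKEN = "<PAD>"


class AminoAcidVocabulary:
    """Token set {PAD, 20 standard amino acids, X}; PAD has index 0 and any
    unrecognized letter maps to X."""

    def __init__(self) -> None:
        self.tokens: list[str] = [PAD_TOKEN] + list(AMINO_ACIDS) + [UNKNOWN_TOKEN]
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index_of(self, letter: str) -> int:
        return self._index.get(letter, self._index[UNKNOWN_TOKEN])

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class CooccurrenceMatrix:
    """Symmetric token-token co-occurrence counts over the non-PAD tokens
    (20 amino acids + X), with 1/distance weighting inside the window."""

    matrix: np.ndarray  # (21, 21), non-negative reals
    window_size: int
    tokens: list[str]   # row/column labels, vocabulary order without PAD


@dataclass
class EmbeddingMatrix:
    """Dense embeddings indexed by the full vocabulary (PAD row = zeros)."""

    matrix: np.ndarray  # (|V|, d)
    vocab: AminoAcidVocabulary

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def save_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for token, row in zip(self.vocab.tokens, self.matrix):
                values = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{token}\t{values}\n")

    @classmethod
    def load_tsv(cls, path) -> "EmbeddingMatrix":
        vocab = AminoAcidVocabulary()
        rows: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows[parts[0]] = np.array([float(v) for v in parts[1:]], dtype=np.float64)
        d = len(next(iter(rows.values())))
        matrix = np.zeros((vocab.size, d))
        for token, row in rows.items():
            matrix[vocab.index_of(token) if token != PAD_TOKEN else 0] = row
        return cls(matrix=matrix, vocab=vocab)


@dataclass
class EncodedProtein:
    """Fixed-length index encoding of one protein sequence (truncated or
    right-padded with PAD to exactly ``len(indices)`` positions)."""

    indices: np.ndarray  # (L,) integer vocabulary indices
    original_length: int


def read_fasta_sequences(path) -> list[str]:
    """Sequences (as plain uppercase strings) from a multi-record FASTA."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def build_cooccurrence(
    corpus: Iterable[str], window_size: int = 5
) -> CooccurrenceMatrix:
    """Accumulate symmetric 1/distance-weighted co-occurrence counts.

    For every pair of positions (i, j), i < j <= i + window_size, within one
    sequence, 1/(j - i) is added to both the (a, b) and (b, a) cells of the
    matrix. Sequences never co-occur across record boundaries.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    vocab = AminoAcidVocabulary()
    tokens = vocab.tokens[1:]  # PAD excluded
    n = len(tokens)
    token_idx = {t: i for i, t in enumerate(tokens)}
    matrix = np.zeros((n, n))
    n_sequences = 0
    for seq in corpus:
        n_sequences += 1
        idx = [token_idx.get(ch, token_idx[UNKNOWN_TOKEN]) for ch in seq.upper()]
        for i in range(len(idx)):
            for j in range(i + 1, min(i + window_size, len(idx) - 1) + 1):
                w = 1.0 / (j - i)
                matrix[idx[i], idx[j]] += w
                matrix[idx[j], idx[i]] += w
    if n_sequences == 0:
        raise ValueError("empty corpus")
    return CooccurrenceMatrix(matrix=matrix, window_size=window_size, tokens=tokens)


def glove_objective(
    cooc: CooccurrenceMatrix,
    w: np.ndarray,
    w_ctx: np.ndarray,
    b: np.ndarray,
    b_ctx: np.ndarray,
    x_max: float = 100.0,
    alpha: float = 0.75,
) -> float:
    """The weighted least-squares objective J evaluated over nonzero cells."""
    rows, cols = np.nonzero(cooc.matrix)
    x = cooc.matrix[rows, cols]
    f = np.minimum(1.0, (x / x_max) ** alpha)
    inner = np.einsum("ij,ij->i", w[rows], w_ctx[cols]) + b[rows] + b_ctx[cols]
    return float(np.sum(f * (inner - np.log(x)) ** 2))


def train_glove(
    cooc: CooccurrenceMatrix,
    d: int = 128,
    epochs: int = 50,
    seed: int = 0,
    learning_rate: float = 0.05,
    x_max: float = 100.0,
    alpha: float = 0.75,
    objective_out: list | None = None,
) -> EmbeddingMatrix:
    """Fit amino-acid embeddings by AdaGrad on the GloVe objective.

    Returns an :class:`EmbeddingMatrix` over the full vocabulary; the
    embedding for each trained token is the sum of its word and context
    vectors, and the PAD row is zero. A fixed seed gives identical output.
    When a list is passed as ``objective_out``, the objective value at
    initialization and after every epoch is appended to it.
    """
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(cooc.tokens)
    w = (rng.random((n, d)) - 0.5) / d
    w_ctx = (rng.random((n, d)) - 0.5) / d
    b = np.zeros(n)
    b_ctx = np.zeros(n)
    gw = np.ones((n, d))
    gw_ctx = np.ones((n, d))
    gb = np.ones(n)
    gb_ctx = np.ones(n)

    rows, cols = np.nonzero(cooc.matrix)
    pairs = np.stack([rows, cols], axis=1)
    if objective_out is not None:
        objective_out.append(
            glove_objective(cooc, w, w_ctx, b, b_ctx, x_max=x_max, alpha=alpha))
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for k in order:
            i, j = pairs[k]
            x = cooc.matrix[i, j]
            f = min(1.0, (x / x_max) ** alpha)
            diff = w[i] @ w_ctx[j] + b[i] + b_ctx[j] - np.log(x)
            # gradient of f * diff^2 wrt each parameter block
            g_common = 2.0 * f * diff
            grad_wi = g_common * w_ctx[j]
            grad_wj = g_common * w[i]
            gw[i] += grad_wi ** 2
            gw_ctx[j] += grad_wj ** 2
            w[i] -= learning_rate * grad_wi / np.sqrt(gw[i])
            w_ctx[j] -= learning_rate * grad_wj / np.sqrt(gw_ctx[j])
            gb[i] += g_common ** 2
            gb_ctx[j] += g_common ** 2
            b[i] -= learning_rate * g_common / np.sqrt(gb[i])
            b_ctx[j] -= learning_rate * g_common / np.sqrt(gb_ctx[j])
        if objective_out is not None:
            objective_out.append(
                glove_objective(cooc, w, w_ctx, b, b_ctx, x_max=x_max, alpha=alpha))

    vocab = AminoAcidVocabulary()
    full = np.zeros((vocab.size, d))
    full[1:] = w + w_ctx  # PAD row (index 0) stays zero
    return EmbeddingMatrix(matrix=full, vocab=vocab)


def encode_protein(
    sequence: str, vocab: AminoAcidVocabulary | None = None, L: int = 1000
) -> EncodedProtein:
    """Map a sequence to exactly L vocabulary indices: truncate past L,
    right-pad with PAD (=0) when shorter. Unknown letters map to X."""
    if not sequence:
        raise ValueError("empty protein sequence")
    if vocab is None:
        vocab = AminoAcidVocabulary()
    indices = np.zeros(L, dtype=np.int64)
    for pos, letter in enumerate(sequence[:L].upper()):
        indices[pos] = vocab.index_of(letter)
    return EncodedProtein(indices=indices, original_length=len(sequence))
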