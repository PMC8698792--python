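"""The EmbedDTI network and its training loop.

Architecture
------------
Three branches are fused for affinity regression:

* **atom branch** — scaled dot-product node attention producing
  H(0) = alpha X, then three graph-convolution layers
  H(l+1) = ReLU(D~^{-1/2} A~ D~^{-1/2} H(l) W(l)) with dims
  N -> N -> 2N -> 4N (N = node feature width), an element-wise max-pool
  over nodes, and two fully connected layers down to a 128-d vector;
* **substructure branch** — same shape over the substructure graph
  (independent parameters, N = 35);
* **protein branch** — amino-acid embedding lookup, three 1-D
  convolutions (1000/256/32 filters, kernels 8/8/3), global max-pool over
  positions, and two fully connected layers down to 128-d.

The three 128-d vectors are concatenated (384-d) and passed through fully
connected layers 384 -> 1024 -> 512 -> 1 with dropout 0.2 to produce the
scalar affinity. Training minimizes MSE with Adam.

The module carries its own small reverse-mode automatic-differentiation
engine over NumPy arrays (everything is kept 2-D; scalars are 1x1). Its
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

from .chem_graphs import (
    ATOM_FEATURE_DIM,
    SUBSTRUCTURE_FEATURE_DIM,
    AtomGraph,
    SubstructureGraph,
    build_atom_graph,
    build_substructure_graph,
    parse_smiles,
    segment_substructures,
)
from .data_pipeline import AffinityRecord
from .protein_embedding import (
    AminoAcidVocabulary,
    EmbeddingMatrix,
    EncodedProtein,
    encode_protein,
)

__all__ = [
    "Tensor",
    "ModelConfig",
    "GraphBranchParams",
    "ProteinBranchParams",
    "FusionHeadParams",
    "ModelParams",
    "TrainState",
    "init_model_params",
    "normalize_adjacency",
    "node_attention",
    "gcn_layer_forward",
    "graph_branch_forward",
    "protein_branch_forward",
    "fuse_and_predict",
    "featurize_record",
    "train_model",
    "predict",
    "predict_featurized",
    "attention_scores",
    "save_checkpoint",
    "load_checkpoint",
    "save_training_log",
]

CHECKPOINT_FORMAT_VERSION = 1


# ==========================================================================
# Reverse-mode autodiff over 2-D NumPy arrays
# ==========================================================================

class Tensor:
    """A node in the computation graph: a float64 array plus backward hooks."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate; grads accumulate into every requires_grad leaf."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data: np.ndarray, parents: tuple[Tensor, ...],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def t_add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))
    return _node(a.data + b.data, (a, b), backward)


def t_sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(-_unbroadcast(g, b.data.shape))
    return _node(a.data - b.data, (a, b), backward)


def t_mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))
    return _node(a.data * b.data, (a, b), backward)


def t_scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        a._accumulate(g * c)
    return _node(a.data * c, (a,), backward)


def t_matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)
    return _node(a.data @ b.data, (a, b), backward)


def t_transpose(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g.T)
    return _node(a.data.T, (a,), backward)


def t_relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)
    return _node(a.data * mask, (a,), backward)


def t_square(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g * 2.0 * a.data)
    return _node(a.data ** 2, (a,), backward)


def t_row_softmax(a: Tensor) -> Tensor:
    shifted = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        a._accumulate(s * (g - (g * s).sum(axis=1, keepdims=True)))
    return _node(s, (a,), backward)


def t_max_over_rows(a: Tensor) -> Tensor:
    """Column-wise max over rows: (n, d) -> (1, d). Ties route the gradient
    to the first maximal row."""
    argmax = a.data.argmax(axis=0)
    out = a.data[argmax, np.arange(a.data.shape[1])][None, :]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[argmax, np.arange(a.data.shape[1])] = g[0]
        a._accumulate(ga)
    return _node(out, (a,), backward)


def t_concat_cols(tensors: Sequence[Tensor]) -> Tensor:
    widths = [t.data.shape[1] for t in tensors]

    def backward(g):
        start = 0
        for t, w in zip(tensors, widths):
            t._accumulate(g[:, start:start + w])
            start += w
    return _node(np.concatenate([t.data for t in tensors], axis=1),
                 tuple(tensors), backward)


def t_embedding(weights: Tensor, indices: np.ndarray) -> Tensor:
    idx = np.asarray(indices, dtype=np.int64)

    def backward(g):
        gw = np.zeros_like(weights.data)
        np.add.at(gw, idx, g)
        weights._accumulate(gw)
    return _node(weights.data[idx], (weights,), backward)


def t_im2col(a: Tensor, k: int) -> Tensor:
    """Unfold (L, C) into sliding windows (L-k+1, k*C) for 1-D convolution."""
    L, C = a.data.shape
    lout = L - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(a.data, (k, C))[:, 0]
    out = windows.reshape(lout, k * C)

    def backward(g):
        ga = np.zeros_like(a.data)
        g3 = g.reshape(lout, k, C)
        for j in range(k):
            ga[j:j + lout] += g3[:, j, :]
        a._accumulate(ga)
    return _node(out, (a,), backward)


def t_conv1d(x: Tensor, weight: Tensor, bias: Tensor, k: int) -> Tensor:
    """1-D convolution: x (L, C), weight (k*C, F), bias (1, F) -> (L-k+1, F)."""
    return t_add(t_matmul(t_im2col(x, k), weight), bias)


def t_mean_all(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g) / n))
    return _node(np.array([[a.data.mean()]]), (a,), backward)


# ==========================================================================
# Configuration
# ==========================================================================

@dataclass
class ModelConfig:
    """All architecture and optimization hyperparameters.

    Defaults are the published training configuration: batch 512, learning
    rate 5e-4, 1500 epochs, dropout 0.2, Adam; protein CNN filters
    (1000, 256, 32) with kernels (8, 8, 3) over length-1000 sequences; GCN
    dims (N, N, 2N) -> (N, 2N, 4N); fusion hidden sizes (1024, 512).
    """

    batch_size: int = 512
    learning_rate: float = 0.0005
    epochs: int = 1500
    dropout: float = 0.2
    protein_len: int = 1000
    embed_dim: int = 128
    conv_filters: tuple[int, int, int] = (1000, 256, 32)
    kernel_sizes: tuple[int, int, int] = (8, 8, 3)
    protein_fc_hidden: int = 1024
    d_k: int = 64
    graph_fc_hidden: int = 1024
    branch_dim: int = 128
    fusion_hidden: tuple[int, int] = (1024, 512)
    seed: int = 0

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A reduced-width configuration for fast CPU experiments and tests;
        the architecture topology is unchanged."""
        base = dict(
            batch_size=8,
            learning_rate=0.002,
            epochs=50,
            dropout=0.0,
            protein_len=64,
            embed_dim=8,
            conv_filters=(8, 8, 8),
            kernel_sizes=(4, 4, 3),
            protein_fc_hidden=16,
            d_k=8,
            graph_fc_hidden=32,
            branch_dim=16,
            fusion_hidden=(32, 16),
        )
        base.update(overrides)
        return cls(**base)

    def gcn_dims(self, n_feat: int) -> list[tuple[int, int]]:
        """(input, output) widths of the three GCN layers for feature width
        N: (N, N), (N, 2N), (2N, 4N)."""
        return [(n_feat, n_feat), (n_feat, 2 * n_feat), (2 * n_feat, 4 * n_feat)]

    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        for key in ("conv_filters", "kernel_sizes", "fusion_hidden"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        for key in ("conv_filters", "kernel_sizes", "fusion_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ==========================================================================
# Parameters
# ==========================================================================

@dataclass
class GraphBranchParams:
    W_Q: Tensor
    W_K: Tensor
    gcn_weights: list[Tensor]           # three matrices, dims per config
    fc1_W: Tensor
    fc1_b: Tensor
    fc2_W: Tensor
    fc2_b: Tensor

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.W_Q": self.W_Q, f"{prefix}.W_K": self.W_K,
               f"{prefix}.fc1_W": self.fc1_W, f"{prefix}.fc1_b": self.fc1_b,
               f"{prefix}.fc2_W": self.fc2_W, f"{prefix}.fc2_b": self.fc2_b}
        for i, w in enumerate(self.gcn_weights):
            out[f"{prefix}.gcn{i}_W"] = w
        return out


@dataclass
class ProteinBranchParams:
    embedding: Tensor                   # (|V|, d), trainable
    conv_weights: list[Tensor]          # flattened (k*C_in, F) kernels
    conv_biases: list[Tensor]
    fc1_W: Tensor
    fc1_b: Tensor
    fc2_W: Tensor
    fc2_b: Tensor

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.embedding": self.embedding,
               f"{prefix}.fc1_W": self.fc1_W, f"{prefix}.fc1_b": self.fc1_b,
               f"{prefix}.fc2_W": self.fc2_W, f"{prefix}.fc2_b": self.fc2_b}
        for i, (w, b) in enumerate(zip(self.conv_weights, self.conv_biases)):
            out[f"{prefix}.conv{i}_W"] = w
            out[f"{prefix}.conv{i}_b"] = b
        return out


@dataclass
class FusionHeadParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    W3: Tensor
    b3: Tensor

    def named(self, prefix: str = "fusion") -> dict[str, Tensor]:
        return {f"{prefix}.W1": self.W1, f"{prefix}.b1": self.b1,
                f"{prefix}.W2": self.W2, f"{prefix}.b2": self.b2,
                f"{prefix}.W3": self.W3, f"{prefix}.b3": self.b3}


@dataclass
class ModelParams:
    atom: GraphBranchParams
    substructure: GraphBranchParams
    protein: ProteinBranchParams
    fusion: FusionHeadParams

    def named(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.atom.named("atom"))
        out.update(self.substructure.named("sub"))
        out.update(self.protein.named("protein"))
        out.update(self.fusion.named("fusion"))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named().items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for name, t in self.named().items():
            t.data = np.array(arrays[name], dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def _zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _init_graph_branch(n_feat: int, config: ModelConfig,
                       rng: np.random.Generator) -> GraphBranchParams:
    dims = config.gcn_dims(n_feat)
    return GraphBranchParams(
        W_Q=_glorot(rng, n_feat, config.d_k),
        W_K=_glorot(rng, n_feat, config.d_k),
        gcn_weights=[_glorot(rng, din, dout) for din, dout in dims],
        fc1_W=_glorot(rng, dims[-1][1], config.graph_fc_hidden),
        fc1_b=_zeros((1, config.graph_fc_hidden)),
        fc2_W=_glorot(rng, config.graph_fc_hidden, config.branch_dim),
        fc2_b=_zeros((1, config.branch_dim)),
    )


def _init_protein_branch(config: ModelConfig, rng: np.random.Generator,
                         pretrained: EmbeddingMatrix | None) -> ProteinBranchParams:
    vocab = AminoAcidVocabulary()
    if pretrained is not None:
        if pretrained.dim != config.embed_dim:
            raise ValueError(
                f"pretrained embedding dim {pretrained.dim} != config embed_dim "
                f"{config.embed_dim}"
            )
        emb = Tensor(pretrained.matrix.copy(), requires_grad=True)
    else:
        emb = Tensor(rng.normal(0.0, 0.1, size=(vocab.size, config.embed_dim)),
                     requires_grad=True)
        emb.data[0] = 0.0  # PAD row starts at zero
    channels = [config.embed_dim, *config.conv_filters]
    conv_w, conv_b = [], []
    for layer, k in enumerate(config.kernel_sizes):
        conv_w.append(_glorot(rng, k * channels[layer], channels[layer + 1]))
        conv_b.append(_zeros((1, channels[layer + 1])))
    return ProteinBranchParams(
        embedding=emb,
        conv_weights=conv_w,
        conv_biases=conv_b,
        fc1_W=_glorot(rng, config.conv_filters[-1], config.protein_fc_hidden),
        fc1_b=_zeros((1, config.protein_fc_hidden)),
        fc2_W=_glorot(rng, config.protein_fc_hidden, config.branch_dim),
        fc2_b=_zeros((1, config.branch_dim)),
    )


def init_model_params(config: ModelConfig, seed: int | None = None,
                      pretrained_embeddings: EmbeddingMatrix | None = None
                      ) -> ModelParams:
    """Seeded Glorot-uniform initialization of every branch; the protein
    embedding table may be seeded from pretrained amino-acid embeddings."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fusion_in = 3 * config.branch_dim
    h1, h2 = config.fusion_hidden
    return ModelParams(
        atom=_init_graph_branch(ATOM_FEATURE_DIM, config, rng),
        substructure=_init_graph_branch(SUBSTRUCTURE_FEATURE_DIM, config, rng),
        protein=_init_protein_branch(config, rng, pretrained_embeddings),
        fusion=FusionHeadParams(
            W1=_glorot(rng, fusion_in, h1), b1=_zeros((1, h1)),
            W2=_glorot(rng, h1, h2), b2=_zeros((1, h2)),
            W3=_glorot(rng, h2, 1), b3=_zeros((1, 1)),
        ),
    )


# ==========================================================================
# Forward passes
# ==========================================================================

def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops:
    D~^{-1/2} (A + I) D~^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    a_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _attention_t(X: Tensor, W_Q: Tensor, W_K: Tensor,
                 d_k: int) -> tuple[Tensor, Tensor]:
    """alpha = row-softmax((X W_Q)(X W_K)^T / sqrt(d_k)); H0 = alpha X."""
    q = t_matmul(X, W_Q)
    k = t_matmul(X, W_K)
    scores = t_scale(t_matmul(q, t_transpose(k)), 1.0 / np.sqrt(d_k))
    alpha = t_row_softmax(scores)
    return alpha, t_matmul(alpha, X)


def node_attention(X: np.ndarray, params: GraphBranchParams,
                   d_k: int | None = None) -> np.ndarray:
    """H(0) = alpha X with scaled dot-product attention; rows of alpha sum
    to 1. Array-in / array-out convenience over the trainable path."""
    d_k = params.W_Q.data.shape[1] if d_k is None else d_k
    _, h0 = _attention_t(Tensor(np.asarray(X, dtype=np.float64)),
                         params.W_Q, params.W_K, d_k)
    return h0.data


def gcn_layer_forward(H: np.ndarray, A_norm: np.ndarray, W: np.ndarray,
                      activation: str = "relu") -> np.ndarray:
    """One propagation step sigma(A_norm H W)."""
    H = np.asarray(H, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if H.shape[1] != W.shape[0] or A_norm.shape[1] != H.shape[0]:
        raise ValueError("shape mismatch in GCN layer")
    out = A_norm @ H @ W
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation in (None, "identity"):
        return out
    raise ValueError(f"unknown activation {activation!r}")


def _graph_branch_t(features: np.ndarray, a_norm: np.ndarray,
                    params: GraphBranchParams, config: ModelConfig) -> Tensor:
    if features.shape[0] < 1:
        raise ValueError("graph must have at least one node")
    X = Tensor(np.asarray(features, dtype=np.float64))
    A = Tensor(a_norm)
    _, h = _attention_t(X, params.W_Q, params.W_K, config.d_k)
    for w in params.gcn_weights:
        h = t_relu(t_matmul(t_matmul(A, h), w))
    pooled = t_max_over_rows(h)
    hid = t_relu(t_add(t_matmul(pooled, params.fc1_W), params.fc1_b))
    return t_add(t_matmul(hid, params.fc2_W), params.fc2_b)


def graph_branch_forward(graph: AtomGraph | SubstructureGraph,
                         params: GraphBranchParams,
                         config: ModelConfig) -> np.ndarray:
    """Graph embedding: attention -> 3 GCN layers -> node max-pool ->
    FC 4N -> hidden -> branch_dim. Returns a (branch_dim,) vector."""
    a_norm = normalize_adjacency(graph.adjacency)
    return _graph_branch_t(graph.features, a_norm, params, config).data[0]


def _protein_branch_t(indices: np.ndarray, params: ProteinBranchParams,
                      config: ModelConfig) -> Tensor:
    h = t_embedding(params.embedding, indices)
    for w, b, k in zip(params.conv_weights, params.conv_biases,
                       config.kernel_sizes):
        h = t_relu(t_conv1d(h, w, b, k))
    pooled = t_max_over_rows(h)
    hid = t_relu(t_add(t_matmul(pooled, params.fc1_W), params.fc1_b))
    return t_add(t_matmul(hid, params.fc2_W), params.fc2_b)


def protein_branch_forward(protein: EncodedProtein,
                           params: ProteinBranchParams,
                           config: ModelConfig) -> np.ndarray:
    """Protein embedding: lookup -> 3 ReLU convolutions -> global max-pool
    -> FC -> FC. Returns a (branch_dim,) vector."""
    if len(protein.indices) != config.protein_len:
        raise ValueError(
            f"encoded length {len(protein.indices)} != config.protein_len "
            f"{config.protein_len}"
        )
    return _protein_branch_t(protein.indices, params, config).data[0]


def _fusion_t(p: Tensor, am: Tensor, cq: Tensor, params: FusionHeadParams,
              config: ModelConfig, train: bool,
              rng: np.random.Generator | None) -> Tensor:
    t = t_concat_cols([p, am, cq])
    h = t_relu(t_add(t_matmul(t, params.W1), params.b1))
    h = _dropout(h, config.dropout, train, rng)
    h = t_relu(t_add(t_matmul(h, params.W2), params.b2))
    h = _dropout(h, config.dropout, train, rng)
    return t_add(t_matmul(h, params.W3), params.b3)


def _dropout(t: Tensor, p: float, train: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not train or p <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= p) / (1.0 - p)
    return t_mul(t, Tensor(mask))


def fuse_and_predict(P: np.ndarray, Am: np.ndarray, Cq: np.ndarray,
                     params: FusionHeadParams,
                     config: ModelConfig | None = None) -> float:
    """Concatenate the three branch vectors (3 x branch_dim) and regress a
    scalar affinity through the fusion head (dropout disabled)."""
    config = config or ModelConfig()
    vecs = []
    for v in (P, Am, Cq):
        v = np.asarray(v, dtype=np.float64).reshape(1, -1)
        vecs.append(Tensor(v))
    expected = params.W1.data.shape[0]
    total = sum(v.data.shape[1] for v in vecs)
    if total != expected:
        raise ValueError(f"fusion input width {total} != expected {expected}")
    return float(_fusion_t(*vecs, params, config, train=False, rng=None).data[0, 0])


# ==========================================================================
# Featurization cache, training and inference
# ==========================================================================

@dataclass
class FeaturizedRecord:
    atom_features: np.ndarray
    atom_a_norm: np.ndarray
    sub_features: np.ndarray
    sub_a_norm: np.ndarray
    protein_indices: np.ndarray
    affinity: float


def featurize_record(record: AffinityRecord,
                     config: ModelConfig) -> FeaturizedRecord:
    """Precompute both molecular graphs and the protein index encoding for
    one record. Raises with the offending record on failure."""
    try:
        mol = parse_smiles(record.drug_smiles)
        atom_graph = build_atom_graph(mol)
        sub_graph = build_substructure_graph(mol, segment_substructures(mol))
    except Exception as exc:
        raise ValueError(
            f"cannot featurize drug {record.drug_id or record.drug_smiles!r}: {exc}"
        ) from exc
    encoded = encode_protein(record.protein_sequence, L=config.protein_len)
    return FeaturizedRecord(
        atom_features=atom_graph.features.astype(np.float64),
        atom_a_norm=normalize_adjacency(atom_graph.adjacency),
        sub_features=sub_graph.features.astype(np.float64),
        sub_a_norm=normalize_adjacency(sub_graph.adjacency),
        protein_indices=encoded.indices,
        affinity=record.affinity,
    )


def _forward_t(feat: FeaturizedRecord, params: ModelParams,
               config: ModelConfig, train: bool,
               rng: np.random.Generator | None) -> Tensor:
    am = _graph_branch_t(feat.atom_features, feat.atom_a_norm,
                         params.atom, config)
    cq = _graph_branch_t(feat.sub_features, feat.sub_a_norm,
                         params.substructure, config)
    p = _protein_branch_t(feat.protein_indices, params.protein, config)
    return _fusion_t(p, am, cq, params.fusion, config, train, rng)


@dataclass
class TrainState:
    """Everything produced by a training run: final parameters, the
    best-validation snapshot, per-epoch loss traces and the seed."""

    config: ModelConfig
    params: ModelParams
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_val_loss: float = float("inf")
    best_params_arrays: dict[str, np.ndarray] | None = None
    epoch: int = 0
    seed: int = 0

    def inference_params(self) -> ModelParams:
        """Best-validation parameters if validation was tracked, else the
        final parameters."""
        if self.best_params_arrays is None:
            return self.params
        best = copy.deepcopy(self.params)
        best.load_state_arrays(self.best_params_arrays)
        return best


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.params.values():
            tensor.grad = None


def _eval_mse(feats: Sequence[FeaturizedRecord], params: ModelParams,
              config: ModelConfig) -> float:
    errors = [
        (float(_forward_t(f, params, config, train=False, rng=None).data[0, 0])
         - f.affinity) ** 2
        for f in feats
    ]
    return float(np.mean(errors))


def train_model(
    dataset: Sequence[AffinityRecord],
    config: ModelConfig,
    seed: int | None = None,
    validation: Sequence[AffinityRecord] | None = None,
    pretrained_embeddings: EmbeddingMatrix | None = None,
    verbose: bool = False,
) -> TrainState:
    """Minibatch Adam on MSE. Per-epoch training (and, when a validation
    set is given, validation) losses are recorded; the parameter snapshot
    with the best validation MSE is kept. Fixed seed => identical traces."""
    if not dataset:
        raise ValueError("empty training dataset")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    feats = [featurize_record(r, config) for r in dataset]
    val_feats = ([featurize_record(r, config) for r in validation]
                 if validation else None)

    params = init_model_params(config, seed=seed,
                               pretrained_embeddings=pretrained_embeddings)
    named = params.named()
    opt = _Adam(named, lr=config.learning_rate)
    state = TrainState(config=config, params=params, seed=seed)

    n = len(feats)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_sq_errors: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                f = feats[idx]
                pred = _forward_t(f, params, config, train=True, rng=rng)
                loss = t_square(t_sub(pred, Tensor([[f.affinity]])))
                epoch_sq_errors.append(float(loss.data[0, 0]))
                loss.backward(np.full((1, 1), 1.0 / len(batch)))
            opt.step()
        state.train_losses.append(float(np.mean(epoch_sq_errors)))
        if val_feats is not None:
            val_mse = _eval_mse(val_feats, params, config)
            state.val_losses.append(val_mse)
            if val_mse < state.best_val_loss:
                state.best_val_loss = val_mse
                state.best_params_arrays = params.state_arrays()
        state.epoch = epoch + 1
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} train_mse={state.train_losses[-1]:.4f}"
            if val_feats is not None:
                msg += f" val_mse={state.val_losses[-1]:.4f}"
            print(msg)
    return state


def predict_featurized(feat: FeaturizedRecord, state: TrainState) -> float:
    params = state.inference_params()
    return float(_forward_t(feat, params, state.config, train=False,
                            rng=None).data[0, 0])


def predict(drug_smiles: str, protein_sequence: str,
            state: TrainState) -> float:
    """Deterministic forward pass (dropout disabled) for one drug-protein
    pair, using the best-validation parameters when available."""
    record = AffinityRecord(drug_smiles=drug_smiles,
                            protein_sequence=protein_sequence, affinity=0.0)
    return predict_featurized(featurize_record(record, state.config), state)


def attention_scores(graph: AtomGraph | SubstructureGraph,
                     params: GraphBranchParams,
                     config: ModelConfig | None = None) -> np.ndarray:
    """Per-node importance in [0, 1]: the column mean of the attention
    matrix alpha, min-max normalized (max -> 1.0, min -> 0.0; a constant
    or single-node case maps to all ones)."""
    config = config or ModelConfig()
    X = Tensor(np.asarray(graph.features, dtype=np.float64))
    alpha, _ = _attention_t(X, params.W_Q, params.W_K, config.d_k)
    raw = alpha.data.mean(axis=0)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


# ==========================================================================
# Checkpoints and logs
# ==========================================================================

def save_checkpoint(state: TrainState, path) -> None:
    """Single-file archive: format version, YAML config, loss traces, final
    and best parameter tensors."""
    arrays: dict[str, np.ndarray] = {
        "__version__": np.array(CHECKPOINT_FORMAT_VERSION),
        "__config__": np.frombuffer(state.config.to_yaml().encode("utf-8"),
                                    dtype=np.uint8),
        "__train_losses__": np.array(state.train_losses),
        "__val_losses__": np.array(state.val_losses),
        "__best_val_loss__": np.array(state.best_val_loss),
        "__epoch__": np.array(state.epoch),
        "__seed__": np.array(state.seed),
    }
    for name, data in state.params.state_arrays().items():
        arrays[f"param/{name}"] = data
    if state.best_params_arrays is not None:
        for name, data in state.best_params_arrays.items():
            arrays[f"best/{name}"] = data
    with open(path, "wb") as fh:  # keep the exact path (savez would add .npz)
        np.savez(fh, **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path) as archive:
        version = int(archive["__version__"])
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {version}")
        config = ModelConfig.from_yaml(
            bytes(archive["__config__"]).decode("utf-8"))
        params = init_model_params(config, seed=0)
        params.load_state_arrays(
            {name[len("param/"):]: archive[name]
             for name in archive.files if name.startswith("param/")})
        best = {name[len("best/"):]: np.array(archive[name])
                for name in archive.files if name.startswith("best/")}
        state = TrainState(
            config=config,
            params=params,
            train_losses=[float(v) for v in archive["__train_losses__"]],
            val_losses=[float(v) for v in archive["__val_losses__"]],
            best_val_loss=float(archive["__best_val_loss__"]),
            best_params_arrays=best or None,
            epoch=int(archive["__epoch__"]),
            seed=int(archive["__seed__"]),
        )
    return state


def save_training_log(state: TrainState, path) -> None:
    """CSV log: epoch, train_mse, val_mse (empty when untracked)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,train_mse,val_mse\n")
        for i, train_mse in enumerate(state.train_losses):
            val = state.val_losses[i] if i < len(state.val_losses) else ""
            fh.write(f"{i + 1},{train_mse!r},{val!r}\n" if val != ""
                     else f"{i + 1},{train_mse!r},\n")
    return None
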