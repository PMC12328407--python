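"""Dynamic label-dependency graph construction (DAME).

The pipeline starts from dataset-level statistics and ends in a learnable,
attention-refined adjacency matrix shared by all samples:

1. count how often label pairs co-occur on the same image (``M``),
2. convert counts to conditional probabilities ``M'[i, j] = P(j | i)``,
3. threshold at ``tau`` to drop low-confidence edges (binary ``A``),
4. reweight so each node keeps ``1 - p`` self-weight and spreads ``p``
   uniformly over its retained neighbours (correlation graph ``N``),
5. refine ``N`` with multi-head scaled-dot-product attention into the final
   adjacency ``P`` consumed by the GCN.

Steps 1-4 are pure statistics computed once per training split; step 5 is
trainable and re-evaluated every forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat
from .nn import Module, parameter, softmax, xavier_uniform

DEFAULT_TAU = 0.4
DEFAULT_P = 0.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMatrix:
    """Binary sample x label matrix plus the label name order."""

    values: np.ndarray
    label_order: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("annotation matrix must be 2-D")
        if self.values.shape[0] < 1:
            raise ValueError("annotation matrix needs at least one sample")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation entries must be binary (0/1)")
        if self.values.shape[1] != len(self.label_order):
            raise ValueError("label_order length must match column count")
        if len(set(self.label_order)) != len(self.label_order):
            raise ValueError("label names must be unique")
        self.values = self.values.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_labels(self) -> int:
        return self.values.shape[1]


@dataclass
class CooccurrenceMatrix:
    """Symmetric pair counts; the diagonal holds per-label totals."""

    counts: np.ndarray
    label_order: list[str]


@dataclass
class ConditionalProbabilityMatrix:
    probs: np.ndarray
    label_order: list[str]


@dataclass
class BinaryAdjacency:
    values: np.ndarray
    tau: float
    label_order: list[str]


@dataclass
class CorrelationGraph:
    """The reweighted graph ``N`` seeding the dynamic adjacency."""

    values: np.ndarray
    p: float
    label_order: list[str]


@dataclass
class AttentionHeadParams:
    """Projection matrices of one scaled-dot-product attention head."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray

    def __post_init__(self):
        if not (self.Wq.shape == self.Wk.shape == self.Wv.shape):
            raise ValueError("Wq, Wk, Wv must share shape (C, D_h)")

    @property
    def d_h(self) -> int:
        return self.Wq.shape[1]


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    label_order: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# statistics pipeline
# ---------------------------------------------------------------------------

def count_cooccurrence(annotations: AnnotationMatrix) -> CooccurrenceMatrix:
    """Count pairwise label co-occurrences over a training split."""
    y = annotations.values
    counts = y.T @ y          # (C, C); diagonal = per-label totals
    return CooccurrenceMatrix(counts=counts, label_order=list(annotations.label_order))


def conditional_probabilities(M: CooccurrenceMatrix) -> ConditionalProbabilityMatrix:
    """Row-conditioned probabilities: ``probs[i, j] = P(j present | i present)``.

    Labels that never occur become isolated self-loop nodes (off-diagonal 0,
    diagonal 1) instead of raising on the zero division.
    """
    counts = np.asarray(M.counts, dtype=np.float64)
    diag = np.diag(counts).copy()
    safe = np.where(diag > 0, diag, 1.0)
    probs = counts / safe[:, None]
    zero = diag == 0
    if zero.any():
        probs[zero, :] = 0.0
        probs[zero, zero] = 1.0
    return ConditionalProbabilityMatrix(probs=probs, label_order=list(M.label_order))


def binarize(Mprime: ConditionalProbabilityMatrix, tau: float = DEFAULT_TAU
             ) -> BinaryAdjacency:
    """Threshold the conditional-probability matrix; boundary maps to 1."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    values = (Mprime.probs >= tau).astype(np.int64)
    return BinaryAdjacency(values=values, tau=tau,
                           label_order=list(Mprime.label_order))


def reweight(A: BinaryAdjacency, p: float = DEFAULT_P) -> CorrelationGraph:
    """Balance self-loops against neighbours.

    Each node keeps weight ``1 - p`` on itself and distributes ``p`` uniformly
    over its retained neighbours; isolated nodes keep a bare self-loop.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    adj = np.asarray(A.values, dtype=np.float64).copy()
    np.fill_diagonal(adj, 0.0)
    degree = adj.sum(axis=1)
    safe = np.where(degree > 0, degree, 1.0)
    values = p * adj / safe[:, None]
    np.fill_diagonal(values, 1.0 - p)
    return CorrelationGraph(values=values, p=p, label_order=list(A.label_order))


def build_correlation_graph(annotations: AnnotationMatrix,
                            tau: float = DEFAULT_TAU,
                            p: float = DEFAULT_P) -> CorrelationGraph:
    """Convenience chain: counts -> conditional probabilities -> A -> N."""
    return reweight(binarize(conditional_probabilities(
        count_cooccurrence(annotations)), tau), p)


# ---------------------------------------------------------------------------
# attention refinement
# ---------------------------------------------------------------------------

def _attention_head_t(N: Tensor, Wq: Tensor, Wk: Tensor, Wv: Tensor) -> Tensor:
    d_h = Wq.shape[1]
    q, k, v = N @ Wq, N @ Wk, N @ Wv
    scores = (q @ k.T) * (1.0 / np.sqrt(d_h))
    return softmax(scores, axis=-1) @ v


def attention_head(N: CorrelationGraph | np.ndarray,
                   params: AttentionHeadParams) -> np.ndarray:
    """One scaled-dot-product head: ``softmax(QK^T / sqrt(D_h)) V``."""
    mat = N.values if isinstance(N, CorrelationGraph) else np.asarray(N)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("N must be a square C x C matrix")
    if params.Wq.shape[0] != mat.shape[0]:
        raise ValueError(f"head projections expect C={params.Wq.shape[0]} rows, "
                         f"graph has C={mat.shape[0]}")
    return _attention_head_t(Tensor(mat), Tensor(params.Wq), Tensor(params.Wk),
                             Tensor(params.Wv)).data


def attention_matrix(N: CorrelationGraph | np.ndarray,
                     params: AttentionHeadParams) -> np.ndarray:
    """The intermediate row-stochastic C x C attention matrix of one head."""
    mat = N.values if isinstance(N, CorrelationGraph) else np.asarray(N)
    q = mat @ params.Wq
    k = mat @ params.Wk
    scores = q @ k.T / np.sqrt(params.d_h)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _build_subgraph_t(N: Tensor, heads: Sequence[tuple[Tensor, Tensor, Tensor]],
                      Wo: Tensor, gain: Tensor | None = None,
                      residual: bool = False) -> Tensor:
    outs = [_attention_head_t(N, *h) for h in heads]
    g = concat(outs, axis=1) @ Wo
    if residual:
        g = N + (g * gain if gain is not None else g)
    return g.relu()


def build_subgraph(N: CorrelationGraph | np.ndarray,
                   heads: Sequence[AttentionHeadParams],
                   Wo: np.ndarray) -> AdjacencyMatrix:
    """One attention subgraph ``G_j``: concat all heads, project back to C x C,
    clamp negatives to zero."""
    mat = N.values if isinstance(N, CorrelationGraph) else np.asarray(N)
    C = mat.shape[0]
    total = sum(h.d_h for h in heads)
    Wo = np.asarray(Wo)
    if Wo.shape != (total, C):
        raise ValueError(f"projection must map {total} -> {C}, got {Wo.shape}")
    labels = N.label_order if isinstance(N, CorrelationGraph) else []
    out = _build_subgraph_t(
        Tensor(mat), [(Tensor(h.Wq), Tensor(h.Wk), Tensor(h.Wv)) for h in heads],
        Tensor(Wo))
    return AdjacencyMatrix(values=out.data, label_order=list(labels))


def compose_adjacency(subgraphs: Sequence[AdjacencyMatrix | np.ndarray],
                      normalize: bool = True) -> AdjacencyMatrix:
    """Left-to-right product of the subgraphs, rectified and (optionally)
    row-normalized to unit row sums."""
    if len(subgraphs) == 0:
        raise ValueError("need at least one subgraph")
    mats = [g.values if isinstance(g, AdjacencyMatrix) else np.asarray(g)
            for g in subgraphs]
    labels = next((list(g.label_order) for g in subgraphs
                   if isinstance(g, AdjacencyMatrix) and g.label_order), [])
    prod = mats[0]
    for m in mats[1:]:
        prod = prod @ m
    prod = np.maximum(prod, 0.0)
    if normalize:
        rows = prod.sum(axis=1, keepdims=True)
        prod = prod / np.where(rows > 0, rows, 1.0)
    return AdjacencyMatrix(values=prod, label_order=labels)


def complexity_estimate(C: int, d: int) -> int:
    """Attention weight count ``C * C * d`` for C labels at head dimension d."""
    if C < 1 or d < 1:
        raise ValueError("C and d must be positive integers")
    return int(C) * int(C) * int(d)


# ---------------------------------------------------------------------------
# trainable module
# ---------------------------------------------------------------------------

class DynamicGraph(Module):
    """Learnable graph-transformer refinement of the correlation graph ``N``.

    ``k`` independent multi-head attention blocks each emit one subgraph
    ``G_j``; their ordered matrix product, rectified and row-normalized, is
    the adjacency ``P`` handed to the GCN.  Each block is an identity-at-init
    residual, ``G_j = relu(N + gain_j * Concat(heads) Wo)`` with ``gain_j``
    starting at 0, so before any training ``P`` reproduces the statistical
    graph structure and the attention pathway fades in as its gains grow.
    """

    def __init__(self, n_labels: int, k: int = 2, heads: int = 4,
                 d_h: int = 64, *, rng: np.random.Generator):
        super().__init__()
        self.n_labels, self.k, self.heads, self.d_h = n_labels, k, heads, d_h
        for j in range(k):
            for i in range(heads):
                for tag in ("q", "k", "v"):
                    w = parameter(xavier_uniform((n_labels, d_h), rng,
                                                 fan_in=n_labels, fan_out=d_h))
                    setattr(self, f"W{tag}_{j}_{i}", w)
            wo = parameter(xavier_uniform((heads * d_h, n_labels), rng,
                                          fan_in=heads * d_h, fan_out=n_labels))
            setattr(self, f"Wo_{j}", wo)
            setattr(self, f"gain_{j}", parameter(np.zeros(1)))

    def subgraph(self, N: Tensor, j: int) -> Tensor:
        heads = [(getattr(self, f"Wq_{j}_{i}"), getattr(self, f"Wk_{j}_{i}"),
                  getattr(self, f"Wv_{j}_{i}")) for i in range(self.heads)]
        return _build_subgraph_t(N, heads, getattr(self, f"Wo_{j}"),
                                 gain=getattr(self, f"gain_{j}"), residual=True)

    def forward(self, N: Tensor | np.ndarray | CorrelationGraph) -> Tensor:
        if isinstance(N, CorrelationGraph):
            N = N.values
        if not isinstance(N, Tensor):
            N = Tensor(N)
        prod = None
        for j in range(self.k):
            g = self.subgraph(N, j)
            prod = g if prod is None else prod @ g
        prod = prod.relu()
        rows = prod.sum(axis=1, keepdims=True)
        # unit row sums; all-zero rows divide by 1 (GCN self-loops cover them)
        denom = rows + Tensor((rows.data <= 0).astype(np.float64))
        return prod / denom

    def adjacency(self, N: CorrelationGraph | np.ndarray) -> AdjacencyMatrix:
        """Numpy convenience: the current P for a given correlation graph."""
        labels = N.label_order if isinstance(N, CorrelationGraph) else []
        return AdjacencyMatrix(values=self.forward(N).data,
                               label_order=list(labels))
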