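"""Label semantics: text preprocessing, word-vector embedding, and the
two-layer GCN that turns label embeddings into per-label classifiers.

Label names are tokenized, stop-word filtered and Porter-stemmed; each label
node is embedded as the mean of its tokens' 300-dimensional word vectors
(GloVe text format).  A two-layer graph convolution over the dynamic
adjacency ``P`` maps the C x 300 embedding matrix to the C x D label
classifier ``W`` that is fused with the pooled image feature.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import stem
from .autodiff import Tensor
from .nn import Module, parameter, xavier_uniform

logger = logging.getLogger(__name__)

EMBED_DIM = 300

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")


# ---------------------------------------------------------------------------
# text preprocessing
# ---------------------------------------------------------------------------

@dataclass
class LabelVocabulary:
    labels: list[str]
    tokens: list[list[str]] = field(default_factory=list)


def _tokenize(label: str) -> list[str]:
    return [t for t in _TOKEN_SPLIT.split(label.lower()) if t]


def preprocess_labels(labels: list[str]) -> LabelVocabulary:
    """Tokenize, drop English stop words, Porter-stem each label name.

    If filtering+stemming would leave a label with no tokens, the raw
    lowercased tokens are kept so every graph node stays embeddable.
    """
    token_lists = []
    for label in labels:
        raw = _tokenize(label)
        if not raw:
            raise ValueError(f"label {label!r} contains no tokens")
        processed = [stem(t) for t in raw if t not in ENGLISH_STOP_WORDS]
        token_lists.append(processed if processed else raw)
    return LabelVocabulary(labels=list(labels), tokens=token_lists)


# ---------------------------------------------------------------------------
# word vectors
# ---------------------------------------------------------------------------

def read_embedding_table(path: str | Path) -> dict[str, np.ndarray]:
    """Parse a GloVe-format text file: ``token v1 ... vN`` per line."""
    table: dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            vec = np.array(parts[1:], dtype=np.float64)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"inconsistent embedding dimensions in {path}: "
                    f"{vec.size} vs {dim} for token {parts[0]!r}")
            table[parts[0]] = vec
    return table


def write_embedding_table(table: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for token, vec in table.items():
            fh.write(token + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def _oov_vector(token: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic unit vector for an out-of-vocabulary token."""
    rng = np.random.default_rng((seed + zlib.crc32(token.encode())) % (2 ** 31))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def embed_labels(vocab: LabelVocabulary, table: dict[str, np.ndarray],
                 seed: int = 0) -> np.ndarray:
    """C x 300 label embedding matrix: mean of each label's token vectors.

    Out-of-vocabulary tokens fall back to a seeded random unit vector so the
    pipeline stays deterministic; each fallback is logged.
    """
    dims = {v.shape[0] for v in table.values()}
    if len(dims) > 1:
        raise ValueError(f"embedding table has mixed dimensions: {sorted(dims)}")
    dim = dims.pop() if dims else EMBED_DIM
    rows = []
    for label, tokens in zip(vocab.labels, vocab.tokens):
        vecs = []
        for tok in tokens:
            if tok in table:
                vecs.append(table[tok])
            else:
                logger.warning("token %r of label %r not in embedding table; "
                               "using seeded random unit vector", tok, label)
                vecs.append(_oov_vector(tok, dim, seed))
        rows.append(np.mean(vecs, axis=0))
    return np.stack(rows)


def cosine_similarity(vi: np.ndarray, vj: np.ndarray) -> float:
    """cos(v_i, v_j) = v_i . v_j / (|v_i| |v_j|)."""
    vi = np.asarray(vi, dtype=np.float64)
    vj = np.asarray(vj, dtype=np.float64)
    ni, nj = np.linalg.norm(vi), np.linalg.norm(vj)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(vi @ vj / (ni * nj), -1.0, 1.0))


def cosine_similarity_matrix(H0: np.ndarray) -> np.ndarray:
    """All pairwise label-embedding cosines (exported for inspection)."""
    norms = np.linalg.norm(H0, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("cosine similarity is undefined for a zero vector")
    unit = H0 / norms
    return np.clip(unit @ unit.T, -1.0, 1.0)


def cosine_correlation_graph(H0: np.ndarray, p: float = 0.2) -> np.ndarray:
    """Optional cosine-edge seed graph in the same form as the statistical
    correlation graph: diagonal 1-p, nonnegative off-diagonal edges from
    clipped cosine similarity, row mass p per non-isolated node."""
    sims = np.maximum(cosine_similarity_matrix(H0), 0.0)
    np.fill_diagonal(sims, 0.0)
    rows = sims.sum(axis=1, keepdims=True)
    out = p * sims / np.where(rows > 0, rows, 1.0)
    np.fill_diagonal(out, 1.0 - p)
    return out


# ---------------------------------------------------------------------------
# graph convolution
# ---------------------------------------------------------------------------

def _gcn_propagate(P: Tensor) -> Tensor:
    """Symmetric-normalized propagation matrix D^-1/2 (P + I) D^-1/2."""
    C = P.shape[0]
    A = P + Tensor(np.eye(C))
    d = A.sum(axis=1) ** -0.5
    return A * d.reshape(C, 1) * d.reshape(1, C)


def _gcn_layer_t(H: Tensor, P: Tensor, Wl: Tensor, activate: bool,
                 slope: float = 0.2) -> Tensor:
    out = _gcn_propagate(P) @ H @ Wl
    return out.leaky_relu(slope) if activate else out


def gcn_layer(H: np.ndarray, P: np.ndarray, Wl: np.ndarray,
              activate: bool = True) -> np.ndarray:
    """One GCN layer over adjacency P (self-loops and symmetric degree
    normalization applied internally); LeakyReLU(0.2) if ``activate``."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if (P < 0).any():
        raise ValueError("adjacency must be nonnegative (rectify upstream)")
    H = np.asarray(H, dtype=np.float64)
    if H.shape[0] != P.shape[0]:
        raise ValueError("H row count must match adjacency size")
    Wl = np.asarray(Wl, dtype=np.float64)
    if Wl.shape[0] != H.shape[1]:
        raise ValueError("weight rows must match feature dimension")
    return _gcn_layer_t(Tensor(H), Tensor(P), Tensor(Wl), activate).data


def gcn_forward(H0: np.ndarray, P: np.ndarray, W0: np.ndarray,
                W1: np.ndarray) -> np.ndarray:
    """Two stacked layers: nonlinear hidden layer then linear classifier
    output ``W`` (C x D), one classifier row per label."""
    hidden = gcn_layer(H0, P, W0, activate=True)
    return gcn_layer(hidden, P, W1, activate=False)


class GCNHead(Module):
    """Trainable two-layer GCN producing the label classifier matrix."""

    def __init__(self, in_dim: int = EMBED_DIM, hidden: int = 1024,
                 out_dim: int = 2048, *, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.hidden, self.out_dim = in_dim, hidden, out_dim
        self.W0 = parameter(xavier_uniform((in_dim, hidden), rng,
                                           fan_in=in_dim, fan_out=hidden))
        self.W1 = parameter(xavier_uniform((hidden, out_dim), rng,
                                           fan_in=hidden, fan_out=out_dim))

    def forward(self, H0: Tensor, P: Tensor) -> Tensor:
        if (P.data < 0).any():
            raise ValueError("adjacency must be nonnegative")
        h = _gcn_layer_t(H0, P, self.W0, activate=True)
        return _gcn_layer_t(h, P, self.W1, activate=False)
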