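"""Model assembly, loss, training recipe, and the multi-label metric suite.

The full classifier fuses the backbone's pooled image feature ``x`` with the
GCN-produced label classifier matrix ``W`` as per-label logits ``yhat = W x``
and trains end to end with multi-label binary cross-entropy.  Two optimizer
groups carry their own learning rates: the graph branch (attention + GCN)
and the CNN branch, following the recipe of SGD momentum 0.9, weight decay
1e-4, step decay x0.1 every 30 epochs and early stopping on validation mAP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .dame import CorrelationGraph, DynamicGraph
from .nn import SGD, Module
from .semantics import GCNHead
from .wtbackbone import Backbone, BackboneSpec

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# fusion and loss
# ---------------------------------------------------------------------------

def fuse(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-label logits ``yhat = W x`` (batched: one row of scores per image)."""
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        if W.shape[1] != x.shape[0]:
            raise ValueError(f"classifier is Cx{W.shape[1]} but feature has "
                             f"length {x.shape[0]}")
        return W @ x
    if W.shape[1] != x.shape[1]:
        raise ValueError("feature dimension mismatch")
    return x @ W.T


def _softplus_t(z: Tensor) -> Tensor:
    # log(1 + exp(z)) = max(z, 0) + log(1 + exp(-|z|)), numerically stable
    absz = z.relu() + (-z).relu()
    return z.relu() + (1.0 + (-absz).exp()).log()


def bce_loss_t(logits: Tensor, y: np.ndarray, reduction: str = "mean"
               ) -> Tensor:
    """Differentiable multi-label BCE (negative log-likelihood, minimized).

    ``reduction='mean'`` averages over labels (the convention of the recipe
    this training setup follows, where the per-class average keeps gradient
    scale independent of C); ``'sum'`` sums over labels as the loss is
    usually printed.  Both average over the batch.
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    yt = Tensor(y)
    per_entry = yt * _softplus_t(-logits) + (1.0 - yt) * _softplus_t(logits)
    reduced = per_entry.sum(axis=-1)
    if reduction == "mean":
        reduced = reduced * (1.0 / y.shape[-1])
    return reduced.mean() if per_entry.ndim > 1 else reduced


def bce_loss(yhat: np.ndarray, y: np.ndarray, reduction: str = "mean"
             ) -> float:
    """Numpy wrapper around :func:`bce_loss_t` (logit-space scores)."""
    return float(bce_loss_t(Tensor(np.asarray(yhat, dtype=np.float64)), y,
                            reduction).data)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """All-points-interpolated AP over the descending-score ranking.

    Ties are broken by stable index order.  Raises on a column with no
    positive example (callers skip and record those labels).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    hits = truth[order].astype(np.float64)
    cum = np.cumsum(hits)
    precision_at_hit = cum[hits > 0] / (np.flatnonzero(hits) + 1)
    return float(precision_at_hit.sum() / n_pos)


def auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    from scipy.stats import rankdata
    ranks = rankdata(scores)          # average ranks handle ties as 1/2
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def mean_average_precision(scores: np.ndarray, truth: np.ndarray
                           ) -> tuple[float, list[int]]:
    """mAP in percent over labels with at least one positive; returns the
    skipped label indices alongside."""
    scores, truth = np.atleast_2d(scores), np.atleast_2d(truth)
    aps, skipped = [], []
    for c in range(truth.shape[1]):
        if truth[:, c].sum() == 0:
            skipped.append(c)
            continue
        aps.append(average_precision(scores[:, c], truth[:, c]))
    if not aps:
        raise ValueError("no label has a positive example")
    return 100.0 * float(np.mean(aps)), skipped


def overall_and_classwise_metrics(scores: np.ndarray, truth: np.ndarray,
                                  threshold: float = 0.5) -> dict[str, float]:
    """Pooled (OP/OR/OF1) and class-averaged (CP/CR/CF1) precision, recall
    and F1 at a fixed decision threshold in sigmoid space.

    F1 values are harmonic means of their aggregated precision and recall.
    Undefined ratios (no predicted / no actual positives) count as 0 and are
    logged.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth)).astype(bool)
    pred = scores >= threshold

    def _ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            logger.debug("%s undefined (zero denominator); reporting 0", what)
            return 0.0
        return num / den

    tp = (pred & truth).sum()
    op = _ratio(tp, pred.sum(), "overall precision")
    orr = _ratio(tp, truth.sum(), "overall recall")
    of1 = _ratio(2 * op * orr, op + orr, "overall F1")

    tp_c = (pred & truth).sum(axis=0).astype(np.float64)
    cp = float(np.mean([_ratio(tp_c[c], pred[:, c].sum(), "class precision")
                        for c in range(truth.shape[1])]))
    cr = float(np.mean([_ratio(tp_c[c], truth[:, c].sum(), "class recall")
                        for c in range(truth.shape[1])]))
    cf1 = _ratio(2 * cp * cr, cp + cr, "class F1")
    return {"OP": float(op), "OR": float(orr), "OF1": float(of1),
            "CP": cp, "CR": cr, "CF1": float(cf1)}


@dataclass
class MetricReport:
    """Full multi-label evaluation summary."""

    mAP: float                       # percent, [0, 100]
    OP: float
    OR: float
    OF1: float
    CP: float
    CR: float
    CF1: float
    auc_per_class: dict[str, float] = field(default_factory=dict)
    auc_mean: float = float("nan")
    skipped_labels: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def table(self) -> str:
        rows = [("mAP", f"{self.mAP:8.3f}")]
        rows += [(k, f"{getattr(self, k):8.4f}")
                 for k in ("OP", "OR", "OF1", "CP", "CR", "CF1")]
        rows.append(("AUC", f"{self.auc_mean:8.4f}"))
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def compute_metrics(logits: np.ndarray, truth: np.ndarray,
                    label_names: list[str] | None = None,
                    threshold: float = 0.5) -> MetricReport:
    """Evaluate logits against binary truth (sigmoid applied internally)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth))
    C = truth.shape[1]
    names = label_names or [f"label_{i}" for i in range(C)]
    probs = 1.0 / (1.0 + np.exp(-logits))
    mAP, skipped = mean_average_precision(logits, truth)
    prf = overall_and_classwise_metrics(probs, truth, threshold)
    aucs: dict[str, float] = {}
    skipped_auc: set[int] = set(skipped)
    for c in range(C):
        col = truth[:, c]
        if col.sum() in (0, len(col)):
            skipped_auc.add(c)
            continue
        aucs[names[c]] = auc(logits[:, c], col)
    auc_mean = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return MetricReport(mAP=mAP, auc_per_class=aucs, auc_mean=auc_mean,
                        skipped_labels=[names[c] for c in sorted(skipped_auc)],
                        **prf)


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

class MedDGTN(Module):
    """Dual-branch classifier: wavelet-conv backbone + dynamic label graph.

    Parameters are split into a CNN branch (the backbone) and a graph branch
    (graph-transformer attention + GCN), each trained with its own learning
    rate.  The correlation graph ``N`` and the label embedding matrix ``H0``
    are fixed inputs computed from the training annotations and label names.
    """

    def __init__(self, H0: np.ndarray, N: CorrelationGraph | np.ndarray,
                 backbone_spec: BackboneSpec | None = None, k: int = 2,
                 heads: int = 4, d_h: int = 64, gcn_hidden: int = 1024,
                 seed: int = 0):
        super().__init__()
        nmat = N.values if isinstance(N, CorrelationGraph) else np.asarray(N)
        self.label_order = list(N.label_order) if isinstance(N, CorrelationGraph) \
            else [f"label_{i}" for i in range(nmat.shape[0])]
        self.n_labels = nmat.shape[0]
        if H0.shape[0] != self.n_labels:
            raise ValueError("H0 rows must match label count")
        spec = backbone_spec or BackboneSpec.default()
        rng = np.random.default_rng(seed + 1)
        self.backbone = Backbone(spec, seed=seed)
        self.graph = DynamicGraph(self.n_labels, k=k, heads=heads, d_h=d_h,
                                  rng=rng)
        self.gcn = GCNHead(H0.shape[1], gcn_hidden, spec.final_channels,
                           rng=rng)
        self.H0 = np.asarray(H0, dtype=np.float64)
        self.N = nmat.astype(np.float64)

    def cnn_parameters(self):
        return list(self.backbone.parameters())

    def graph_parameters(self):
        return list(self.graph.parameters()) + list(self.gcn.parameters())

    def label_classifier(self) -> Tensor:
        """The C x D classifier W from the current dynamic graph."""
        P = self.graph(Tensor(self.N))
        return self.gcn(Tensor(self.H0), P)

    def forward(self, images: Tensor) -> Tensor:
        x = self.backbone(images)                 # (n, D)
        W = self.label_classifier()               # (C, D)
        return x @ W.T                            # logits (n, C)

    def predict_proba(self, images: np.ndarray, batch_size: int = 16
                      ) -> np.ndarray:
        """Sigmoid label probabilities for a stack of images (eval mode)."""
        was_training = self.training
        self.eval()
        out = []
        for start in range(0, len(images), batch_size):
            batch = Tensor(np.asarray(images[start:start + batch_size],
                                      dtype=np.float64))
            out.append(1.0 / (1.0 + np.exp(-self.forward(batch).data)))
        self.train(was_training)
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """The training recipe (all values overridable)."""

    epochs: int = 100
    batch_size: int = 16
    lr_graph: float = 0.5
    lr_cnn: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 1e-4
    decay_every: int = 30            # multiply both LRs by decay_factor
    decay_factor: float = 0.1
    patience: int = 10               # early stopping on validation mAP
    threshold: float = 0.5
    clip_norm: float | None = 1.0    # global gradient-norm clip (None = off)
    seed: int = 0
    augment: bool = False

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.decay_every < 1:
            raise ValueError("invalid training configuration")


def augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flip (p=0.5) and multi-scale random crop resized
    back to the input size (scales 1.0 / 0.875 / 0.75 / 0.66)."""
    from skimage.transform import resize

    out = images.copy()
    size = images.shape[-1]
    scales = (1.0, 0.875, 0.75, 0.66)
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        scale = scales[rng.integers(len(scales))]
        if scale < 1.0:
            crop = max(8, int(round(size * scale)))
            top = rng.integers(0, size - crop + 1)
            left = rng.integers(0, size - crop + 1)
            patch = out[i, :, top:top + crop, left:left + crop]
            out[i] = resize(patch, (patch.shape[0], size, size),
                            order=1, mode="reflect", anti_aliasing=False,
                            preserve_range=True)
    return out


@dataclass
class TrainResult:
    history: list[dict]
    best_epoch: int
    best_map: float
    state: dict[str, np.ndarray]


def train(model: MedDGTN, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig | None = None,
          val_images: np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          checkpoint_path: str | Path | None = None,
          log_jsonl: str | Path | None = None,
          start_epoch: int = 0) -> TrainResult:
    """Train with dual learning-rate groups; returns per-epoch metric log.

    Validation defaults to the training split when no validation set is
    given (the overfitting-check regime for synthetic data).  The best
    validation-mAP weights are restored into ``model`` before returning.
    """
    config = config or TrainConfig()
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("training dataset is empty")
    if val_images is None:
        val_images, val_labels = images, labels

    rng = np.random.default_rng(config.seed)
    optimizer = SGD([
        {"params": model.graph_parameters(), "lr": config.lr_graph},
        {"params": model.cnn_parameters(), "lr": config.lr_cnn},
    ], momentum=config.momentum, weight_decay=config.weight_decay,
        clip_norm=config.clip_norm)

    history: list[dict] = []
    best_map, best_epoch = -np.inf, -1
    best_state = model.state_dict()
    stale = 0
    log_fh = open(log_jsonl, "a") if log_jsonl else None
    try:
        for epoch in range(start_epoch, config.epochs):
            if epoch > 0 and epoch % config.decay_every == 0:
                optimizer.scale_lr(config.decay_factor)
                logger.info("epoch %d: learning rates decayed by %.2g",
                            epoch, config.decay_factor)
            model.train()
            order = rng.permutation(len(images))
            losses = []
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                batch = images[idx]
                if config.augment:
                    batch = augment_batch(batch, rng)
                logits = model(Tensor(batch))
                loss = bce_loss_t(logits, labels[idx])
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            train_logits = _batched_logits(model, images, config.batch_size)
            val_logits = _batched_logits(model, val_images, config.batch_size)
            train_map, _ = mean_average_precision(train_logits, labels)
            val_map, _ = mean_average_precision(val_logits, val_labels)
            entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                     "train_mAP": train_map, "val_mAP": val_map}
            history.append(entry)
            logger.info("epoch %(epoch)d loss %(loss).4f train mAP "
                        "%(train_mAP).2f val mAP %(val_mAP).2f", entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if val_map > best_map:
                best_map, best_epoch, stale = val_map, epoch, 0
                best_state = model.state_dict()
                if checkpoint_path is not None:
                    save_checkpoint(model, checkpoint_path, epoch=epoch,
                                    val_map=val_map)
            else:
                stale += 1
                if stale >= config.patience:
                    logger.info("early stopping at epoch %d (best %d)",
                                epoch, best_epoch)
                    break
    finally:
        if log_fh:
            log_fh.close()
    model.load_state_dict(best_state)
    return TrainResult(history=history, best_epoch=best_epoch,
                       best_map=float(best_map), state=best_state)


def _batched_logits(model: MedDGTN, images: np.ndarray,
                    batch_size: int) -> np.ndarray:
    model.eval()
    outs = []
    for start in range(0, len(images), batch_size):
        outs.append(model(Tensor(images[start:start + batch_size])).data)
    model.train()
    return np.concatenate(outs, axis=0)


def evaluate(model: MedDGTN, images: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> MetricReport:
    if len(images) == 0:
        raise ValueError("evaluation dataset is empty")
    logits = _batched_logits(model, np.asarray(images, dtype=np.float64), 16)
    model.eval()
    return compute_metrics(logits, labels, label_names=model.label_order,
                           threshold=threshold)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MedDGTN, path: str | Path, epoch: int = -1,
                    val_map: float = float("nan")) -> None:
    """Single-file binary checkpoint (npz) with a version field."""
    meta = {"version": CHECKPOINT_VERSION, "epoch": epoch, "val_map": val_map,
            "label_order": model.label_order}
    arrays = {"param:" + k: v for k, v in model.state_dict().items()}
    arrays["H0"] = model.H0
    arrays["N"] = model.N
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(),
                                       dtype=np.uint8), **arrays)


def load_checkpoint(model: MedDGTN, path: str | Path) -> dict:
    """Restore weights in place; returns the checkpoint metadata."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version in {path}")
            state = {k[6:]: data[k] for k in data.files
                     if k.startswith("param:")}
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    model.load_state_dict(state)
    return meta
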