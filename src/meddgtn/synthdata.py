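"""Seeded synthetic multi-label imaging datasets with planted structure.

Two planted properties make every downstream mechanism testable without any
external download:

* **Label co-occurrence blocks** — labels are partitioned into blocks; each
  sample activates one block's labels with probability ``p_within`` and the
  rest with ``p_between``, planting a block structure that the DAME graph
  pipeline should recover.
* **Frequency-localized lesion signals** — each active label contributes a
  broad Gaussian-envelope signal at a label-specific grid location whose
  carrier is a label-specific low-spatial-frequency oriented cosine, plus
  shared high-frequency pixel noise.  The characteristic low-frequency
  content is what makes each label detectable by a pooled, translation-
  equivariant CNN and what the wavelet backbone is designed to emphasize.

A companion generator emits a deterministic GloVe-format embedding table
whose same-block tokens share a common component, so semantic similarity
mirrors the planted co-occurrence blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .dame import AnnotationMatrix
from .semantics import preprocess_labels, write_embedding_table

_MAX_RESAMPLE = 1000


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    C: int = 8
    n: int = 500
    blocks: list[list[int]] | None = None      # default: two equal blocks
    p_within: float = 0.6
    p_between: float = 0.05
    image_size: int = 112
    lesion_sigma_low: float | None = None      # default: image_size / 6
    noise_sigma: float = 0.05
    seed: int = 0
    label_names: list[str] | None = None

    def __post_init__(self):
        if self.blocks is None:
            half = self.C // 2
            self.blocks = [list(range(half)), list(range(half, self.C))]
        flat = sorted(i for b in self.blocks for i in b)
        if flat != list(range(self.C)):
            raise ValueError("blocks must partition the label indices 0..C-1")
        for prob in (self.p_within, self.p_between):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.lesion_sigma_low is None:
            self.lesion_sigma_low = self.image_size / 6.0
        if self.label_names is None:
            self.label_names = [f"cond{i:02d}" for i in range(self.C)]
        if len(self.label_names) != self.C:
            raise ValueError("need one label name per class")

    def block_of(self, label: int) -> int:
        for b, members in enumerate(self.blocks):
            if label in members:
                return b
        raise KeyError(label)


@dataclass
class SynthDataset:
    images: np.ndarray            # (n, 3, H, W) floats in [0, 1]
    annotations: AnnotationMatrix
    spec: SynthSpec

    @property
    def labels(self) -> np.ndarray:
        return self.annotations.values.astype(np.float64)


def sample_labels(spec: SynthSpec) -> AnnotationMatrix:
    """Draw the planted block co-occurrence annotation matrix (seeded)."""
    rng = np.random.default_rng(spec.seed)
    rows = np.zeros((spec.n, spec.C), dtype=np.int64)
    for s in range(spec.n):
        for _ in range(_MAX_RESAMPLE):
            block = spec.blocks[rng.integers(len(spec.blocks))]
            probs = np.full(spec.C, spec.p_between)
            probs[block] = spec.p_within
            row = (rng.random(spec.C) < probs).astype(np.int64)
            if row.any():
                rows[s] = row
                break
        else:
            raise ValueError("could not draw a non-empty label set; "
                             "are all activation probabilities zero?")
    return AnnotationMatrix(values=rows, label_order=list(spec.label_names))


def label_template(label: int, spec: SynthSpec) -> np.ndarray:
    """The deterministic H x W signal one label contributes.

    A Gaussian envelope centred on the label's grid cell modulated by a
    label-specific low-frequency oriented cosine carrier.
    """
    size = spec.image_size
    grid = int(np.ceil(np.sqrt(spec.C)))
    gy, gx = divmod(label, grid)
    cy = (gy + 0.5) * size / grid
    cx = (gx + 0.5) * size / grid
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    envelope = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                      / (2.0 * spec.lesion_sigma_low ** 2))
    freq = 1.0 + (label % 4)                  # cycles across the image
    theta = np.pi * label / max(spec.C, 1)
    carrier = 0.5 * (1.0 + np.cos(2.0 * np.pi * freq
                                  * (np.cos(theta) * xx + np.sin(theta) * yy)
                                  / size))
    return 0.8 * envelope * carrier


def render_image(label_vector: np.ndarray, spec: SynthSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one (3, H, W) image for an active-label vector.

    Active labels add their templates; iid Gaussian pixel noise of scale
    ``noise_sigma`` supplies the high-frequency component; values are
    clipped to [0, 1] and replicated to three channels.
    """
    label_vector = np.asarray(label_vector)
    if label_vector.sum() < 1:
        raise ValueError("render_image needs at least one active label")
    canvas = np.zeros((spec.image_size, spec.image_size))
    for label in np.flatnonzero(label_vector):
        canvas += label_template(int(label), spec)
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return np.repeat(canvas[None], 3, axis=0)


def make_dataset(spec: SynthSpec, out_dir: str | Path | None = None
                 ) -> SynthDataset:
    """Sample annotations, render all images, optionally write to disk.

    On disk the dataset is ``images/<image_id>.png`` plus ``labels.csv`` in
    the pipe-separated annotation dialect the CLI reads back.
    """
    annotations = sample_labels(spec)
    rng = np.random.default_rng(spec.seed + 1)
    images = np.stack([render_image(row, spec, rng)
                       for row in annotations.values])
    ds = SynthDataset(images=images, annotations=annotations, spec=spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        lines = ["image_id,labels"]
        for i, row in enumerate(annotations.values):
            image_id = f"img_{i:05d}"
            arr = (np.clip(images[i, 0], 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr, mode="L").convert("RGB").save(
                img_dir / f"{image_id}.png")
            active = [annotations.label_order[j] for j in np.flatnonzero(row)]
            lines.append(f"{image_id},{'|'.join(active)}")
        (out_dir / "labels.csv").write_text("\n".join(lines) + "\n")
    return ds


GLOVE_ENTRY_STD = 0.38    # typical per-coordinate spread of GloVe-300


def make_embeddings(labels: list[str], blocks: list[list[int]] | None = None,
                    dim: int = 300, seed: int = 0, mixing: float = 0.5,
                    path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Deterministic GloVe-format fixture table for the given label names.

    Each preprocessed token receives a seeded random vector scaled to the
    typical norm of real 300-d GloVe vectors (entry spread ~0.38, norm ~6.5)
    so downstream layers see realistic input magnitudes.  Tokens belonging
    to labels of the same block share an added block component (weight
    ``mixing``), so within-block cosine similarity exceeds between-block.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    vocab = preprocess_labels(labels)
    rng = np.random.default_rng(seed)
    scale = GLOVE_ENTRY_STD * np.sqrt(dim)
    block_vecs = {}
    if blocks:
        for b in range(len(blocks)):
            v = rng.standard_normal(dim)
            block_vecs[b] = v / np.linalg.norm(v)
    token_block: dict[str, int] = {}
    if blocks:
        for b, members in enumerate(blocks):
            for label_idx in members:
                for tok in vocab.tokens[label_idx]:
                    token_block.setdefault(tok, b)
    table: dict[str, np.ndarray] = {}
    for tokens in vocab.tokens:
        for tok in tokens:
            if tok in table:
                continue
            v = rng.standard_normal(dim)
            v = v / np.linalg.norm(v)
            if tok in token_block:
                v = v + mixing * block_vecs[token_block[tok]]
                v = v / np.linalg.norm(v)
            table[tok] = scale * v
    if path is not None:
        write_embedding_table(table, path)
    return table
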