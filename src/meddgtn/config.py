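"""Hierarchical run configuration (YAML round-trippable, unknown keys
rejected).  Defaults follow the published recipe where one exists: tau 0.4,
p 0.2, SGD momentum 0.9 with weight decay 1e-4, learning rates 0.5 (graph) /
0.03 (CNN), 100 epochs, batch 16, step decay x0.1 every 30 epochs."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GraphConfig(_Strict):
    tau: float = 0.4
    p: float = 0.2
    k: int = 2                  # attention blocks (subgraphs)
    heads: int = 4
    d_h: int = 64
    init: str = "statistics"    # "statistics" or "cosine" blend
    cosine_weight: float = 0.0


class GCNConfig(_Strict):
    hidden: int = 1024
    embed_dim: int = 300


class BackboneConfig(_Strict):
    profile: str = "default"    # "default" (448 px) or "reduced" (112 px)
    image_size: int | None = None
    final_channels: int | None = None
    levels: int | None = None
    normalize: bool = False     # ImageNet channel normalization on load


class TrainSection(_Strict):
    epochs: int = 100
    batch_size: int = 16
    lr_graph: float = 0.5
    lr_cnn: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 1.0e-4
    decay_every: int = 30
    decay_factor: float = 0.1
    patience: int = 10
    threshold: float = 0.5
    clip_norm: float | None = 1.0
    augment: bool = False


class RunConfig(_Strict):
    seed: int = 0
    graph: GraphConfig = GraphConfig()
    gcn: GCNConfig = GCNConfig()
    backbone: BackboneConfig = BackboneConfig()
    train: TrainSection = TrainSection()

    def dump(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.dump())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def backbone_spec(self):
        from .wtbackbone import BackboneSpec, WTConvSpec

        if self.backbone.profile == "reduced":
            spec = BackboneSpec.reduced()
        elif self.backbone.profile == "default":
            spec = BackboneSpec.default()
        else:
            raise ValueError(f"unknown backbone profile "
                             f"{self.backbone.profile!r}")
        if self.backbone.image_size is not None:
            spec.input_size = self.backbone.image_size
        if self.backbone.final_channels is not None:
            spec.final_channels = self.backbone.final_channels
        if self.backbone.levels is not None:
            spec.wtconv = WTConvSpec(levels=self.backbone.levels,
                                     kernel=spec.wtconv.kernel,
                                     wavelet=spec.wtconv.wavelet)
        return spec

    def train_config(self):
        from .model import TrainConfig

        t = self.train
        return TrainConfig(epochs=t.epochs, batch_size=t.batch_size,
                           lr_graph=t.lr_graph, lr_cnn=t.lr_cnn,
                           momentum=t.momentum, weight_decay=t.weight_decay,
                           decay_every=t.decay_every,
                           decay_factor=t.decay_factor, patience=t.patience,
                           threshold=t.threshold, clip_norm=t.clip_norm,
                           seed=self.seed, augment=t.augment)
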