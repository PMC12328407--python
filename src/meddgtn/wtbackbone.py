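"""Wavelet-convolution dense backbone producing the pooled image feature.

A DenseNet-style network whose composite layers replace the plain 3x3
convolution with a WTConv: the feature map is decomposed by a cascaded
orthonormal wavelet transform, each frequency subband is filtered with a
small depthwise kernel, and the cascade is recombined through the inverse
transform.  Repeated decomposition widens the receptive field cheaply and
emphasizes the low-frequency content where subtle pathology tends to live.

The default profile takes a 3x448x448 image to a ``final_channels`` x 14 x 14
map and global-average-pools it to the D = 2048 feature fused with the label
classifiers.  A reduced profile (112 px input, two shallow blocks) serves
desk-scale experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .autodiff import Tensor
from .nn import (BatchNorm2d, Conv2d, DepthwiseConv2d, Module, PointwiseConv,
                 avg_pool2d, global_avg_pool, parameter)

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# public single-plane transforms (PyWavelets-backed)
# ---------------------------------------------------------------------------

def dwt2(plane: np.ndarray, wavelet: str = "haar"):
    """Single-level orthonormal 2-D DWT of one plane.

    Returns ``(LL, LH, HL, HH)`` at half resolution.  Odd extents are
    reflect-padded to even (logged) before the periodized transform.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0 or plane.ndim != 2:
        raise ValueError("dwt2 expects a non-empty 2-D plane")
    pad_h, pad_w = plane.shape[0] % 2, plane.shape[1] % 2
    if pad_h or pad_w:
        logger.debug("dwt2: reflect-padding odd plane %s", plane.shape)
        plane = np.pad(plane, ((0, pad_h), (0, pad_w)), mode="reflect")
    LL, (LH, HL, HH) = pywt.dwt2(plane, wavelet, mode="periodization")
    return LL, LH, HL, HH


def idwt2(subbands, wavelet: str = "haar",
          out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Inverse of :func:`dwt2`; ``out_shape`` crops padding for odd planes."""
    LL, LH, HL, HH = (np.asarray(b, dtype=np.float64) for b in subbands)
    if not (LL.shape == LH.shape == HL.shape == HH.shape):
        raise ValueError("subbands must share one shape")
    plane = pywt.idwt2((LL, (LH, HL, HH)), wavelet, mode="periodization")
    if out_shape is not None:
        plane = plane[: out_shape[0], : out_shape[1]]
    return plane


# ---------------------------------------------------------------------------
# differentiable Haar transform on (N, C, H, W) tensors
# ---------------------------------------------------------------------------

def _slicer(ndim: int, axis: int, sl: slice) -> tuple:
    idx = [slice(None)] * ndim
    idx[axis] = sl
    return tuple(idx)


def _haar_split(x: Tensor, axis: int) -> tuple[Tensor, Tensor]:
    even = x[_slicer(x.ndim, axis, slice(0, None, 2))]
    odd = x[_slicer(x.ndim, axis, slice(1, None, 2))]
    return (even + odd) * (1.0 / _SQRT2), (odd - even) * (1.0 / _SQRT2)


def _haar_merge(lo: Tensor, hi: Tensor, axis: int) -> Tensor:
    even = (lo - hi) * (1.0 / _SQRT2)
    odd = (lo + hi) * (1.0 / _SQRT2)
    return even.interleave2(odd, axis)


def dwt2_t(x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor, tuple[int, int]]:
    """Differentiable orthonormal Haar DWT over the last two axes."""
    h, w = x.shape[-2], x.shape[-1]
    pad_h, pad_w = h % 2, w % 2
    if pad_h or pad_w:
        pads = [(0, 0)] * (x.ndim - 2) + [(0, pad_h), (0, pad_w)]
        x = x.pad_reflect(pads)
    lo_h, hi_h = _haar_split(x, axis=-1)
    LL, LH = _haar_split(lo_h, axis=-2)
    HL, HH = _haar_split(hi_h, axis=-2)
    return LL, LH, HL, HH, (h, w)


def idwt2_t(LL: Tensor, LH: Tensor, HL: Tensor, HH: Tensor,
            out_hw: tuple[int, int]) -> Tensor:
    lo_h = _haar_merge(LL, LH, axis=-2)
    hi_h = _haar_merge(HL, HH, axis=-2)
    x = _haar_merge(lo_h, hi_h, axis=-1)
    h, w = out_hw
    if x.shape[-2] != h or x.shape[-1] != w:
        x = x[_slicer(x.ndim, -2, slice(0, h))][_slicer(x.ndim, -1, slice(0, w))]
    return x


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class WTConvSpec:
    levels: int = 2
    kernel: int = 3
    wavelet: str = "haar"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")


@dataclass
class WTDenseBlockSpec:
    num_layers: int = 6
    growth: int = 48

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("a dense block needs at least one layer")


@dataclass
class BackboneSpec:
    blocks: list[WTDenseBlockSpec] = field(
        default_factory=lambda: [WTDenseBlockSpec() for _ in range(4)])
    stem_channels: int = 64
    compression: float = 0.5
    final_channels: int = 2048
    input_size: int = 448
    wtconv: WTConvSpec = field(default_factory=WTConvSpec)

    @classmethod
    def default(cls) -> "BackboneSpec":
        return cls()

    @classmethod
    def reduced(cls, image_size: int = 112, final_channels: int = 64
                ) -> "BackboneSpec":
        """Desk-scale profile: two shallow blocks on 112-px inputs."""
        return cls(blocks=[WTDenseBlockSpec(num_layers=2, growth=16)
                           for _ in range(2)],
                   stem_channels=24, final_channels=final_channels,
                   input_size=image_size, wtconv=WTConvSpec(levels=1))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class WTConv(Module):
    """Depthwise wavelet convolution (channel- and shape-preserving).

    One small depthwise kernel filters the input directly (base path); a
    cascade decomposes the running low-frequency band ``levels`` times,
    filters every subband depthwise, and reconstructs upward through the
    inverse transform.  The output averages the two paths, with a learnable
    per-channel gain (initialized at 1) on the cascade, so identity kernels
    reproduce the input exactly while the frequency-selective path is live
    from the first forward pass.
    """

    def __init__(self, channels: int, spec: WTConvSpec | None = None, *,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec or WTConvSpec()
        if self.spec.wavelet != "haar":
            raise NotImplementedError(
                "the differentiable cascade supports the Haar family only; "
                "use dwt2/idwt2 for other wavelets")
        self.channels = channels
        self.base = DepthwiseConv2d(channels, self.spec.kernel, rng=rng)
        for lv in range(self.spec.levels):
            for band in ("ll", "lh", "hl", "hh"):
                self.register(f"conv_{band}_{lv}",
                              DepthwiseConv2d(channels, self.spec.kernel,
                                              rng=rng))
        self.gain = parameter(np.ones(channels))

    def _cascade(self, x: Tensor, level: int) -> Tensor:
        if level == self.spec.levels:
            return x
        LL, LH, HL, HH, hw = dwt2_t(x)
        deeper = self._cascade(getattr(self, f"conv_ll_{level}")(LL), level + 1)
        return idwt2_t(deeper,
                       getattr(self, f"conv_lh_{level}")(LH),
                       getattr(self, f"conv_hl_{level}")(HL),
                       getattr(self, f"conv_hh_{level}")(HH), hw)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        if min(h, w) < 2 ** self.spec.levels:
            raise ValueError(f"spatial dims {h}x{w} too small for "
                             f"{self.spec.levels} wavelet levels")
        base = self.base(x)
        cascade = self._cascade(x, 0)
        return (base + cascade * self.gain.reshape(1, self.channels, 1, 1)) \
            * 0.5


class WTDenseLayer(Module):
    """Composite layer BN -> ReLU -> 1x1 (to growth channels) -> 3x3 WTConv."""

    def __init__(self, in_ch: int, growth: int, wtspec: WTConvSpec, *,
                 rng: np.random.Generator):
        super().__init__()
        self.bn = BatchNorm2d(in_ch)
        self.proj = PointwiseConv(in_ch, growth, rng=rng)
        self.wtconv = WTConv(growth, wtspec, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.wtconv(self.proj(self.bn(x).relu()))


class WTDenseBlock(Module):
    """Densely connected stack: each layer's output is concatenated onto the
    running channel stack (DenseNet connectivity)."""

    def __init__(self, in_ch: int, spec: WTDenseBlockSpec,
                 wtspec: WTConvSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.out_channels = in_ch + spec.num_layers * spec.growth
        ch = in_ch
        for i in range(spec.num_layers):
            self.register(f"layer_{i}",
                          WTDenseLayer(ch, spec.growth, wtspec, rng=rng))
            ch += spec.growth

    @property
    def layers(self) -> list[WTDenseLayer]:
        return [getattr(self, f"layer_{i}")
                for i in range(self.spec.num_layers)]

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import concat
        for i in range(self.spec.num_layers):
            out = getattr(self, f"layer_{i}")(x)
            x = concat([x, out], axis=1)
        return x


class Transition(Module):
    """1x1 channel compression followed by 2x2 average pooling (stride 2)."""

    def __init__(self, in_ch: int, compression: float = 0.5, *,
                 rng: np.random.Generator):
        super().__init__()
        self.out_channels = max(1, int(in_ch * compression))
        self.conv = PointwiseConv(in_ch, self.out_channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] % 2 or x.shape[-2] % 2:
            logger.debug("transition: reflect-padding odd map %s", x.shape)
        return avg_pool2d(self.conv(x))


class Backbone(Module):
    """Stem -> WTDense blocks with transitions -> 1x1 projection -> GAP."""

    def __init__(self, spec: BackboneSpec | None = None,
                 seed: int = 0):
        super().__init__()
        self.spec = spec or BackboneSpec.default()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.stem_conv = Conv2d(3, s.stem_channels, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = BatchNorm2d(s.stem_channels)
        ch = s.stem_channels
        n = len(s.blocks)
        for i, bspec in enumerate(s.blocks):
            block = WTDenseBlock(ch, bspec, s.wtconv, rng=rng)
            self.register(f"block_{i}", block)
            ch = block.out_channels
            if i < n - 1:
                tr = Transition(ch, s.compression, rng=rng)
                self.register(f"transition_{i}", tr)
                ch = tr.out_channels
        self.final_bn = BatchNorm2d(ch)
        self.final_proj = PointwiseConv(ch, s.final_channels, rng=rng)

    @property
    def blocks(self) -> list[WTDenseBlock]:
        return [getattr(self, f"block_{i}")
                for i in range(len(self.spec.blocks))]

    def feature_map(self, images: Tensor) -> Tensor:
        """The pre-pool map, ``final_channels`` x H' x W'."""
        n, c, h, w = images.shape
        expected = self.spec.input_size
        if c != 3 or h != expected or w != expected:
            raise ValueError(f"backbone expects 3x{expected}x{expected} "
                             f"images, got {c}x{h}x{w}")
        x = self.stem_conv(images)
        x = self.stem_bn(x).relu()
        x = x.pad_reflect(((0, 0), (0, 0), (1, 1), (1, 1))).maxpool2d(3, 2)
        nblocks = len(self.spec.blocks)
        for i in range(nblocks):
            x = getattr(self, f"block_{i}")(x)
            if i < nblocks - 1:
                x = getattr(self, f"transition_{i}")(x)
        return self.final_proj(self.final_bn(x).relu())

    def forward(self, images: Tensor) -> Tensor:
        """Pooled image features, shape (N, final_channels)."""
        return global_avg_pool(self.feature_map(images))


def backbone_forward(image: np.ndarray, backbone: Backbone | None = None,
                     seed: int = 0) -> np.ndarray:
    """Run one 3 x H x W image through a backbone; returns the pooled feature."""
    backbone = backbone or Backbone(seed=seed)
    backbone.eval()
    x = Tensor(np.asarray(image, dtype=np.float64)[None])
    return backbone(x).data[0]
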