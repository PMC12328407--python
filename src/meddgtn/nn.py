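"""Minimal neural-network layer library used by the Med-DGTN model.

Layers mirror the familiar torch.nn surface (``Module``/``parameters``/
``train``/``eval``) but hold :class:`~meddgtn.autodiff.Tensor` parameters and
run on the in-repo autodiff engine.  Only what the architecture needs is
implemented: dense and depthwise 2-D convolutions with reflection padding,
batch normalization, pooling, and SGD with momentum, weight decay and
independent parameter groups.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .autodiff import Tensor


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator,
                   fan_in: int | None = None,
                   fan_out: int | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    if fan_in is None:
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (reflect-pad odd extents)."""
    _, _, h, w = x.shape
    if h % 2 or w % 2:
        x = x.pad_reflect(((0, 0), (0, 0), (0, h % 2), (0, w % 2)))
    return (x[:, :, 0::2, 0::2] + x[:, :, 1::2, 0::2]
            + x[:, :, 0::2, 1::2] + x[:, :, 1::2, 1::2]) * 0.25


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3))


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name.replace(".", "_"), module)
        return module

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, arr in getattr(self, "_buffers", {}).items():
            yield prefix + name, arr
        for mname, mod in self._modules.items():
            yield from mod.buffers(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- flat state dict of plain arrays (parameters + buffers) -----------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + name: arr.copy() for name, arr in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, arr in state.items():
            if key.startswith("buf:"):
                target = bufs[key[4:]]
                target[...] = arr
            else:
                p = params[key]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {arr.shape}")
                p.data = arr.astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


class Conv2d(Module):
    """Dense 2-D convolution (im2col) with reflection padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, *, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        self.weight = parameter(
            xavier_uniform((out_ch, in_ch, kernel, kernel), rng,
                           fan_in=fan_in, fan_out=out_ch * kernel * kernel))
        self.bias = parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        if self.pad:
            x = x.pad_reflect(((0, 0), (0, 0), (self.pad, self.pad),
                               (self.pad, self.pad)))
        cols = x.unfold((self.kernel, self.kernel), self.stride)
        wmat = self.weight.reshape(self.out_ch, -1).T          # (C_in*k*k, C_out)
        out = cols @ wmat                                      # (N, L, C_out)
        if self.bias is not None:
            out = out + self.bias.reshape(1, 1, self.out_ch)
        out_h = (h + 2 * self.pad - self.kernel) // self.stride + 1
        out_w = (w + 2 * self.pad - self.kernel) // self.stride + 1
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, out_h, out_w)


class PointwiseConv(Module):
    """1x1 convolution, implemented as a per-pixel matmul."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator,
                 bias: bool = False):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = parameter(xavier_uniform((in_ch, out_ch), rng,
                                               fan_in=in_ch, fan_out=out_ch))
        self.bias = parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, self.out_ch)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution via shifted reflect-padded slices."""

    def __init__(self, channels: int, kernel: int = 3, *,
                 rng: np.random.Generator, init: str = "xavier"):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        self.channels, self.kernel = channels, kernel
        if init == "dirac":
            w = np.zeros((channels, kernel, kernel))
            w[:, kernel // 2, kernel // 2] = 1.0
        elif init == "zero":
            w = np.zeros((channels, kernel, kernel))
        else:
            w = xavier_uniform((channels, kernel, kernel), rng,
                               fan_in=kernel * kernel, fan_out=kernel * kernel)
        self.weight = parameter(w)

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import depthwise_conv2d
        return depthwise_conv2d(x, self.weight)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, identity_affine: bool = False):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.identity_affine = identity_affine
        if not identity_affine:
            self.gamma = parameter(np.ones(channels))
            self.beta = parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1 - self.momentum
            rm += self.momentum * mu.data.reshape(-1)
            rv *= 1 - self.momentum
            rv += self.momentum * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        if self.identity_affine:
            return xhat
        return xhat * self.gamma.reshape(1, self.channels, 1, 1) \
            + self.beta.reshape(1, self.channels, 1, 1)


class SGD:
    """SGD with momentum, weight decay, per-group learning rates and an
    optional global gradient-norm clip (applied across all groups)."""

    def __init__(self, groups: Sequence[dict], momentum: float = 0.9,
                 weight_decay: float = 1e-4,
                 clip_norm: float | None = None):
        self.groups = [{"params": list(g["params"]), "lr": float(g["lr"])}
                       for g in groups]
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity: dict[int, np.ndarray] = {}

    def _clip(self) -> None:
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for g in self.groups for p in g["params"]
                            if p.grad is not None))
        if total > self.clip_norm > 0:
            scale = self.clip_norm / total
            for g in self.groups:
                for p in g["params"]:
                    if p.grad is not None:
                        p.grad = p.grad * scale

    def step(self) -> None:
        if self.clip_norm is not None:
            self._clip()
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad + self.weight_decay * p.data
                v = self._velocity.get(id(p))
                v = self.momentum * v + g if v is not None else g
                self._velocity[id(p)] = v
                p.data = p.data - lr * v

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def scale_lr(self, factor: float) -> None:
        for group in self.groups:
            group["lr"] *= factor
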