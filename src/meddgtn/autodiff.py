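"""Compact reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the operator set the Med-DGTN layers need:
broadcasting arithmetic, matmul, elementwise nonlinearities, reductions,
shape surgery (slice / reshape / transpose / concat / pad / roll) and a few
image-specific primitives (unfold for im2col convolution, max-pooling,
zero-interleaving for inverse wavelet transforms).  Gradients are dense
``float64`` arrays accumulated on leaf tensors by :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that NumPy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward: Callable) -> "Tensor":
        needs = any(p.requires_grad for p in parents)
        if not needs:
            return Tensor(data)
        return Tensor(data, requires_grad=True, _prev=parents, _backward=backward)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g,
                                          other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        scale = np.where(pos, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accum(g * scale)

        return Tensor._make(self.data * scale, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max_lastaxis(self):
        """Maximum along the last axis (sub-gradient to first argmax)."""
        idx = self.data.argmax(axis=-1)
        out_data = np.take_along_axis(self.data, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx[..., None], np.asarray(g)[..., None],
                              axis=-1)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- shape surgery ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        parts = idx if isinstance(idx, tuple) else (idx,)
        plain = all(isinstance(p, (slice, int)) for p in parts)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if plain:       # slices never repeat an element
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data.copy(), (self,), backward)

    def roll(self, shift: int, axis: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.roll(np.asarray(g), -shift, axis=axis))
        return Tensor._make(np.roll(self.data, shift, axis=axis), (self,), backward)

    def pad_reflect(self, pad: Sequence[tuple[int, int]]):
        """Reflection padding; ``pad`` gives (before, after) per axis."""
        pad = tuple(tuple(p) for p in pad)
        out_data = np.pad(self.data, pad, mode="reflect")

        def backward(g):
            if self.requires_grad:
                self._accum(_fold_reflect(np.asarray(g), pad))

        return Tensor._make(out_data, (self,), backward)

    def interleave2(self, other: "Tensor", axis: int):
        """Interleave two equal-shaped tensors element-wise along ``axis``.

        Result has doubled extent: out[..., 2k, ...] = self, out[..., 2k+1, ...]
        = other.  This is the upsampling step of the inverse Haar transform.
        """
        other = as_tensor(other)
        shape = list(self.shape)
        shape[axis] *= 2
        out_data = np.empty(shape, dtype=np.float64)
        sl_even = [slice(None)] * len(shape)
        sl_odd = [slice(None)] * len(shape)
        sl_even[axis] = slice(0, None, 2)
        sl_odd[axis] = slice(1, None, 2)
        out_data[tuple(sl_even)] = self.data
        out_data[tuple(sl_odd)] = other.data

        def backward(g):
            g = np.asarray(g)
            if self.requires_grad:
                self._accum(g[tuple(sl_even)])
            if other.requires_grad:
                other._accum(g[tuple(sl_odd)])

        return Tensor._make(out_data, (self, other), backward)

    # -- image primitives -------------------------------------------------
    def unfold(self, kernel: tuple[int, int], stride: int):
        """im2col: (N, C, H, W) -> (N, out_h*out_w, C*kh*kw) patch matrix."""
        n, c, h, w = self.shape
        kh, kw = kernel
        out_h = (h - kh) // stride + 1
        out_w = (w - kw) // stride + 1
        s = self.data.strides
        windows = np.lib.stride_tricks.as_strided(
            self.data,
            shape=(n, c, out_h, out_w, kh, kw),
            strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
            writeable=False,
        )
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h * out_w,
                                                           c * kh * kw)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g).reshape(n, out_h, out_w, c, kh, kw)
            full = np.zeros_like(self.data)
            for i in range(kh):
                for j in range(kw):
                    full[:, :, i:i + out_h * stride:stride,
                         j:j + out_w * stride:stride] += gg[:, :, :, :, i, j] \
                        .transpose(0, 3, 1, 2)
            self._accum(full)

        return Tensor._make(cols.copy(), (self, ), backward)

    def maxpool2d(self, kernel: int, stride: int):
        """Max pooling over (N, C, H, W); input assumed already padded."""
        n, c, h, w = self.shape
        out_h = (h - kernel) // stride + 1
        out_w = (w - kernel) // stride + 1
        s = self.data.strides
        windows = np.lib.stride_tricks.as_strided(
            self.data,
            shape=(n, c, out_h, out_w, kernel, kernel),
            strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
            writeable=False,
        ).reshape(n, c, out_h, out_w, kernel * kernel)
        idx = windows.argmax(axis=-1)
        out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            full = np.zeros_like(self.data)
            ki, kj = np.divmod(idx, kernel)
            ns, cs, hs, ws = np.indices((n, c, out_h, out_w))
            np.add.at(full, (ns, cs, hs * stride + ki, ws * stride + kj), gg)
            self._accum(full)

        return Tensor._make(out_data.copy(), (self,), backward)

    # -- autograd driver ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a "
                                 "scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._prev:          # free non-leaf grads early
                    node.grad = None


def _fold_reflect(gg: np.ndarray, pad) -> np.ndarray:
    """Adjoint of reflection padding: fold borders onto their sources."""
    gg = gg.copy()
    for ax, (before, after) in enumerate(pad):
        if before:
            sl_src = [slice(None)] * gg.ndim
            sl_dst = [slice(None)] * gg.ndim
            sl_src[ax] = slice(before - 1, None, -1)
            sl_dst[ax] = slice(before + 1, 2 * before + 1)
            gg[tuple(sl_dst)] += gg[tuple(sl_src)]
        if after:
            n = gg.shape[ax]
            sl_src = [slice(None)] * gg.ndim
            sl_dst = [slice(None)] * gg.ndim
            sl_src[ax] = slice(n - 1, n - after - 1, -1)
            sl_dst[ax] = slice(n - 2 * after - 1, n - after - 1)
            gg[tuple(sl_dst)] += gg[tuple(sl_src)]
        trim = [slice(None)] * gg.ndim
        trim[ax] = slice(before, gg.shape[ax] - after)
        gg = gg[tuple(trim)]
    return gg


def depthwise_conv2d(x: Tensor, weight: Tensor) -> Tensor:
    """Per-channel k x k correlation with reflection padding.

    ``x`` is (N, C, H, W), ``weight`` is (C, k, k); output shape equals the
    input shape.  A dedicated primitive (rather than a composition of shifts
    and multiplies) because it sits in the innermost loop of the backbone.
    """
    n, c, h, w = x.shape
    ck, kh, kw = weight.shape
    if ck != c or kh != kw or kh % 2 == 0:
        raise ValueError("weight must be (C, k, k) with odd k matching x")
    p = kh // 2
    pad = ((0, 0), (0, 0), (p, p), (p, p))
    xp = np.pad(x.data, pad, mode="reflect")
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, h, w, kh, kw),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]), writeable=False)
    out_data = np.einsum("nchwij,cij->nchw", windows, weight.data,
                         optimize=True)

    def backward(g):
        g = np.asarray(g)
        if weight.requires_grad:
            weight._accum(np.einsum("nchw,nchwij->cij", g, windows,
                                    optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + h, j:j + w] += \
                        g * weight.data[None, :, i, j, None, None]
            x._accum(_fold_reflect(gxp, pad))

    return Tensor._make(out_data, (x, weight), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        g = np.asarray(g)
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)
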