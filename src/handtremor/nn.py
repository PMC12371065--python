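"""Minimal reverse-mode autodiff on numpy arrays, with the conv/pool layers
used by the classifier branches.

Scope is deliberately small: exactly the operations the GhostNet and
Improved-LinkNet graphs need (dense and depthwise convolution, 2x2 pooling,
nearest upsampling, batch normalization and its weighted-average-pooled
variant, the activation zoo, Adam).  Everything runs on the CPU and is a pure
function of (weights, input), so repeated inference calls are bit-identical.

Gradients are accumulated by a topological sweep over the recorded graph;
convolution forward/backward use ``sliding_window_view`` + ``einsum`` so the
heavy lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "DepthwiseConv2d",
    "Linear",
    "BatchNorm2d",
    "WapBN2d",
    "Sequential",
    "Adam",
    "relu",
    "leaky_relu",
    "elu",
    "swish",
    "sigmoid",
    "avg_pool2d",
    "max_pool2d",
    "upsample_nearest2",
    "global_avg_pool",
    "concat",
    "softmax",
    "cross_entropy",
    "conv2d_forward",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * 0.5 / np.maximum(out.data, 1e-300)
        )
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * np.sign(self.data)
        )
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out


# ---------------------------------------------------------------------------
# activations


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (x.data > 0))
    return out


def leaky_relu(x: Tensor, alpha: float = 0.01) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, alpha * x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g * np.where(x.data > 0, 1.0, alpha)
    )
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))
    out = Tensor(out_data, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g * np.where(pos, 1.0, out_data + alpha)
    )
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * s * (1.0 - s))
    return out


def swish(x: Tensor) -> Tensor:
    """x * sigmoid(x) (a.k.a. SiLU)."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * s, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(
        g * (s + x.data * s * (1.0 - s))
    )
    return out


# ---------------------------------------------------------------------------
# convolution / pooling primitives


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    stride: int = 1,
    pad: int = 0,
) -> np.ndarray:
    """Plain-array dense convolution (correlation), NCHW x (K,C,kh,kw)."""
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _windows(xp, kh, kw, stride)
    out = np.einsum("nchwij,kcij->nkhw", win, w, optimize=True)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _windows(xp, kh, kw, stride)
    out_data = np.einsum("nchwij,kcij->nkhw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _prev=prev)
    n, _, ho, wo = out_data.shape

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nkhw->kcij", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            colgrad = np.einsum("nkhw,kcij->nchwij", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += colgrad[
                        :, :, :, :, i, j
                    ]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    out._backward = bwd
    return out


def depthwise_conv2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0
) -> Tensor:
    """Depthwise convolution: w has shape (C, multiplier, kh, kw)."""
    c, m, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _windows(xp, kh, kw, stride)  # N,C,Ho,Wo,kh,kw
    out_data = np.einsum("nchwij,cmij->ncmhw", win, w.data, optimize=True)
    n, _, _, ho, wo = out_data.shape
    out_data = out_data.reshape(n, c * m, ho, wo)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, _prev=prev)

    def bwd(g):
        gr = g.reshape(n, c, m, ho, wo)
        if w.requires_grad:
            w._accum(np.einsum("nchwij,ncmhw->cmij", win, gr, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            colgrad = np.einsum("ncmhw,cmij->nchwij", gr, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += colgrad[
                        :, :, :, :, i, j
                    ]
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    out._backward = bwd
    return out


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2d needs even spatial dims, got {h}x{w}")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

    out._backward = bwd
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties share the gradient."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(3, 5))
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        mask = blocks == out_data[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        grad_blocks = mask * (g[:, :, :, None, :, None] / counts)
        x._accum(grad_blocks.reshape(n, c, h, w))

    out._backward = bwd
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _prev=(x,))
    n, c, h, w = x.data.shape

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC."""
    return x.mean(axis=(2, 3))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer targets."""
    n, k = logits.data.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    s = logits - shift
    lse = s.exp().sum(axis=1, keepdims=True).log()
    logp = s - lse
    onehot = np.zeros((n, k))
    onehot[np.arange(n), np.asarray(targets, dtype=int)] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class: tracks parameter tensors and submodules by attribute."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            for m in _collect_modules(value):
                mods.extend(m.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat dict of parameter (and running-stat) arrays for checkpointing."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        for j, m in enumerate(self.modules()):
            if isinstance(m, (BatchNorm2d, WapBN2d)):
                out[f"running_mean_{j}"] = m.running_mean
                out[f"running_var_{j}"] = m.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"param_{i}"], dtype=np.float64)
        for j, m in enumerate(self.modules()):
            if isinstance(m, (BatchNorm2d, WapBN2d)):
                m.running_mean = np.asarray(arrays[f"running_mean_{j}"], dtype=np.float64)
                m.running_var = np.asarray(arrays[f"running_var_{j}"], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list["Module"]:
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        trainable: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Tensor(
            he_normal(rng, (out_channels, in_channels, k, k), fan_in),
            requires_grad=trainable,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=trainable) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)

    def n_weight_params(self) -> int:
        return self.weight.data.size


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        multiplier: int,
        kernel_size: int,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Tensor(
            he_normal(rng, (channels, multiplier, k, k), k * k), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(channels * multiplier), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight, self.bias, self.stride, self.pad)

    def n_weight_params(self) -> int:
        return self.weight.data.size


class Linear(Module):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            he_normal(rng, (in_features, out_features), in_features), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Standard per-channel batch normalization ``(Z - mean)/sqrt(var + eps)``."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _stats(self, x: Tensor) -> tuple[Tensor, Tensor]:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            return mean, var
        shape = (1, -1, 1, 1)
        return Tensor(self.running_mean.reshape(shape)), Tensor(
            self.running_var.reshape(shape)
        )

    def forward(self, x: Tensor) -> Tensor:
        mean, var = self._stats(x)
        xhat = (x - mean) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class WapBN2d(Module):
    """Batch normalization modulated by a weighted-average-pooled statistic.

    Per sample and channel, ``S_J = (1 - gamma) * mean(spatial window)`` with
    the window being the full feature map.  The normalized output is
    ``S_J * (Z - mean) / sqrt(var + sigmoid(S_J) + eps)``.  With the pooling
    weight ``gamma = 1`` the statistic vanishes and so does the output - the
    degenerate printed setting - hence the shipped default ``gamma = 0.5``.
    """

    def __init__(
        self, channels: int, gamma: float = 0.5, eps: float = 1e-5, momentum: float = 0.1
    ):
        self.gamma_pool = gamma
        self.eps = eps
        self.momentum = momentum
        self.scale = Tensor(np.ones(channels), requires_grad=True)
        self.shift = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        s_j = x.mean(axis=(2, 3), keepdims=True) * (1.0 - self.gamma_pool)  # (N,C,1,1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        sig = sigmoid(s_j)
        num = x * s_j - mean * s_j
        den = (var + sig + self.eps).sqrt()
        out = num / den
        return out * self.scale.reshape(1, -1, 1, 1) + self.shift.reshape(1, -1, 1, 1)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
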