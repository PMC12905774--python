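"""Minimal reverse-mode tensor autograd on numpy.

Implements exactly the operations the 3D dense convolutional classifier
needs: broadcast add/mul, matmul, ReLU, reshape, channel concatenation,
3D convolution (im2col), batch normalization, average pooling, global mean
pooling, and fused softmax cross-entropy. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` over a topologically sorted tape.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv3d", "batchnorm", "avgpool3d", "global_mean_pool",
           "relu", "matmul", "softmax_cross_entropy", "softmax"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        src_shape = self.data.shape
        out._backward = lambda g: self._accumulate(g.reshape(src_shape))
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))
    mask = x.data > 0
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _node(a.data @ b.data, (a, b))

    def bwd(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    n, c, do, ho, wo = win.shape[:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        n * do * ho * wo, c * k**3
    )
    return cols, (do, ho, wo)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, out_spatial):
    n, c, d, h, w = x_shape
    do, ho, wo = out_spatial
    dxp = np.zeros((n, c, d + 2 * pad, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    for i, j, l in product(range(k), range(k), range(k)):
        dxp[:, :, i:i + do * stride:stride, j:j + ho * stride:stride, l:l + wo * stride:stride] += d6[..., i, j, l]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return dxp


def conv3d(x: Tensor, weight: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution; ``x`` (N, Cin, D, H, W), ``weight`` (Cout, Cin, k, k, k)."""
    cout, cin, k, _, _ = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.data.shape[1]}")
    cols, out_spatial = _im2col(x.data, k, stride, padding)
    w_mat = weight.data.reshape(cout, -1)
    n = x.data.shape[0]
    y = (cols @ w_mat.T).reshape(n, *out_spatial, cout).transpose(0, 4, 1, 2, 3)
    out = _node(np.ascontiguousarray(y), (x, weight))
    x_shape = x.data.shape

    def bwd(g):
        g_mat = g.transpose(0, 2, 3, 4, 1).reshape(-1, cout)
        weight._accumulate((g_mat.T @ cols).reshape(weight.data.shape))
        if x.requires_grad or x._parents:
            dcols = g_mat @ w_mat
            x._accumulate(_col2im(dcols, x_shape, k, stride, padding, out_spatial))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Normalization / pooling / loss
# ---------------------------------------------------------------------------

def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray | None = None,
    running_var: np.ndarray | None = None,
    training: bool = True,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (batch, spatial) axes.

    In eval mode the provided running statistics are used and treated as
    constants in the backward pass.
    """
    axes = (0, 2, 3, 4)
    bshape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(bshape)) / std.reshape(bshape)
    y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    out = _node(y, (x, gamma, beta))

    def bwd(g):
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gs = gamma.data.reshape(bshape) / std.reshape(bshape)
        if training:
            m_mean = g.mean(axis=axes).reshape(bshape)
            mx_mean = (g * xhat).mean(axis=axes).reshape(bshape)
            x._accumulate(gs * (g - m_mean - xhat * mx_mean))
        else:
            x._accumulate(gs * g)

    out._backward = bwd
    return out


def avgpool3d(x: Tensor) -> Tensor:
    """Factor-2 average pooling per spatial axis; axes of size 1 are kept."""
    n, c, d, h, w = x.data.shape
    f = tuple(2 if s >= 2 else 1 for s in (d, h, w))
    dd, hh, ww = d // f[0], h // f[1], w // f[2]
    crop = x.data[:, :, : dd * f[0], : hh * f[1], : ww * f[2]]
    y = crop.reshape(n, c, dd, f[0], hh, f[1], ww, f[2]).mean(axis=(3, 5, 7))
    out = _node(y, (x,))

    def bwd(g):
        dx = np.zeros_like(x.data)
        scale = 1.0 / (f[0] * f[1] * f[2])
        block = g[:, :, :, None, :, None, :, None] * scale
        dx[:, :, : dd * f[0], : hh * f[1], : ww * f[2]] = np.broadcast_to(
            block, (n, c, dd, f[0], hh, f[1], ww, f[2])
        ).reshape(n, c, dd * f[0], hh * f[1], ww * f[2])
        x._accumulate(dx)

    out._backward = bwd
    return out


def global_mean_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1x1, flattened to (N, C)."""
    n, c = x.data.shape[:2]
    spatial = int(np.prod(x.data.shape[2:]))
    out = _node(x.data.reshape(n, c, -1).mean(axis=2), (x,))

    def bwd(g):
        x._accumulate(np.broadcast_to((g / spatial)[:, :, None], (n, c, spatial)).reshape(x.data.shape))

    out._backward = bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    n = logits.data.shape[0]
    p = softmax(logits.data)
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-15, None)))
    out = _node(np.asarray(loss), (logits,))

    def bwd(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(float(g) * d / n)

    out._backward = bwd
    return out
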