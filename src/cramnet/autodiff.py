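"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine backs the whole network stack: dense layers, strided 2-D
convolution (im2col), ReLU/sigmoid gates, global average pooling and a
softmax cross-entropy loss.  It is deliberately small: a ``Tensor`` wraps a
float64 array and remembers how it was produced, and ``backward`` walks the
graph in reverse topological order accumulating gradients.  Gradients are
retained on every node in the graph, which is what Grad-CAM needs (gradients
of a class logit with respect to an intermediate convolutional activation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "matmul", "relu", "sigmoid", "concat", "reshape",
    "conv2d", "global_avg_pool", "softmax", "softmax_cross_entropy",
]


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data : array-like
        Values, stored as float64.
    requires_grad : bool
        Leaf flag; interior nodes inherit it from their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "trainable", "name")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward
        self.trainable = requires_grad  # optimizers may toggle this
        self.name = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # --- graph traversal -------------------------------------------------

    def backward(self, seed=None):
        """Backpropagate from this node.

        ``seed`` defaults to ones (so a scalar loss needs no argument).
        """
        if seed is None:
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()

        def visit(node: Tensor):
            if id(node) in visited or not node.requires_grad:
                return
            visited.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(seed, dtype=np.float64).reshape(self.data.shape).copy()
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # --- operator sugar ---------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self):
        return _sum(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports (n, d) @ (d, h) and vector (d,) @ (d, h)."""
    out_data = a.data @ b.data

    def bwd(g):
        if a.data.ndim == 1:  # vector @ matrix
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += np.outer(a.data, g)
        else:
            if a.requires_grad:
                a.grad += g @ b.data.swapaxes(-1, -2)
            if b.requires_grad:
                b.grad += a.data.swapaxes(-1, -2) @ g

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def bwd(g):
        if x.requires_grad:
            x.grad += g * mask

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def bwd(g):
        if x.requires_grad:
            x.grad += g * s * (1.0 - s)

    return Tensor(s, _parents=(x,), _backward=bwd)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def bwd(g):
        if x.requires_grad:
            x.grad += g.reshape(x.data.shape)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def _sum(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.sum())

    def bwd(g):
        if x.requires_grad:
            x.grad += np.broadcast_to(g, x.data.shape)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


# --- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; x is NCHW, weight is (out_ch, in_ch, kh, kw)."""
    oc, ic, kh, kw = weight.data.shape
    if x.data.shape[1] != ic:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]} channels, kernel expects {ic}")
    cols, (oh, ow) = _im2col(x.data, kh, kw, stride, pad)
    w_mat = weight.data.reshape(oc, -1)
    out_data = (w_mat @ cols).reshape(x.data.shape[0], oc, oh, ow)
    out_data += bias.data.reshape(1, oc, 1, 1)

    def bwd(g):
        g2 = g.reshape(g.shape[0], oc, oh * ow)
        if bias.requires_grad:
            bias.grad += g2.sum(axis=(0, 2))
        if weight.requires_grad:
            weight.grad += np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(weight.data.shape)
        if x.requires_grad:
            dcols = np.einsum("ok,nop->nkp", w_mat, g2)
            x.grad += _col2im(dcols, x.data.shape, kh, kw, stride, pad, oh, ow)

    return Tensor(out_data, _parents=(x, weight, bias), _backward=bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC, averaging over the spatial axes."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def bwd(g):
        if x.requires_grad:
            x.grad += g[:, :, None, None] / (h * w) * np.ones((1, 1, h, w))

    return Tensor(out_data, _parents=(x,), _backward=bwd)


# --- classification head --------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    labels = np.asarray(labels)
    p = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()

    def bwd(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), labels] -= 1.0
            logits.grad += g * d / n

    return Tensor(np.asarray(loss), _parents=(logits,), _backward=bwd)
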