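"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the segmentation and classification
networks need: broadcast elementwise arithmetic, matmul, 2-D convolution
(stride 1, zero 'same' padding), 2x2 max pooling, nearest-neighbour x2
upsampling, channel concatenation, reductions, the usual nonlinearities,
and numerically fused classification losses.  Tensors are float64 NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- reductions and shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    # -- linear algebra ------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    # -- structured ops (NCHW) -----------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None):
        """Stride-1 'same' zero-padded 2-D convolution (cross-correlation).

        x: (N, C, H, W); weight: (O, C, kh, kw) with odd kh, kw;
        bias: (O,) broadcast over space.
        """
        weight = self._lift(weight)
        x = self.data
        w = weight.data
        kh, kw = w.shape[2], w.shape[3]
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
        out_data = np.einsum("nchwij,ocij->nohw", windows, w, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, -1, 1, 1)

        def bw(g):
            if weight.requires_grad:
                weight._accumulate(
                    np.einsum("nchwij,nohw->ocij", windows, g, optimize=True)
                )
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
                gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
                w_flip = w[:, :, ::-1, ::-1]
                self._accumulate(
                    np.einsum("nohwij,ocij->nchw", gwin, w_flip, optimize=True)
                )

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor(out_data, parents=parents, backward=bw)

    def maxpool2(self):
        """2x2 stride-2 max pooling; spatial dims must be even."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2 requires even spatial dimensions")
        blocks = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        out_data = blocks.max(axis=(3, 5))
        argmask = blocks == out_data[:, :, :, None, :, None]
        # break ties toward the first occurrence to keep the gradient exact
        flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.zeros_like(flat)
        idx = flat.argmax(axis=-1)
        np.put_along_axis(first, idx[..., None], 1, axis=-1)
        first = first.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

        def bw(g):
            if self.requires_grad:
                gb = first * g[:, :, :, None, :, None]
                self._accumulate(gb.reshape(n, c, h, w))

        return Tensor(out_data, parents=(self,), backward=bw)

    def upsample2(self):
        """Nearest-neighbour x2 upsampling."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        n, c, h, w = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(
                    g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
                )

        return Tensor(out_data, parents=(self,), backward=bw)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1):
        tensors = [Tensor._lift(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, gg in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(gg)

        return Tensor(out_data, parents=tuple(tensors), backward=bw)

    def channel_mean(self):
        """Mean over the channel axis, keepdim: (N,C,H,W) -> (N,1,H,W)."""
        return self.mean(axis=1, keepdims=True)

    def channel_max(self):
        """Max over the channel axis, keepdim: (N,C,H,W) -> (N,1,H,W)."""
        out_data = self.data.max(axis=1, keepdims=True)
        argmask = self.data == out_data
        first = np.zeros_like(self.data)
        idx = self.data.argmax(axis=1)
        np.put_along_axis(first, idx[:, None], 1, axis=1)

        def bw(g):
            if self.requires_grad:
                self._accumulate(first * g)

        return Tensor(out_data, parents=(self,), backward=bw)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; pass rate 0 (or skip entirely) at eval time."""
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        if rate == 0:
            return self
        keep = (rng.uniform(size=self.data.shape) >= rate) / (1.0 - rate)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return Tensor(self.data * keep, parents=(self,), backward=bw)

    # -- fused losses ---------------------------------------------------------

    def bce_with_logits(self, target: np.ndarray):
        """Mean binary cross-entropy on logits (numerically stable)."""
        z = self.data
        t = np.asarray(target, dtype=np.float64)
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        n = z.size

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (_sigmoid(z) - t) / n)

        return Tensor(loss.mean(), parents=(self,), backward=bw)

    def softmax_cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy of row softmax vs integer labels (N,K)."""
        z = self.data
        labels = np.asarray(labels, dtype=np.int64)
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        p = ez / ez.sum(axis=1, keepdims=True)
        n = z.shape[0]
        nll = -np.log(p[np.arange(n), labels] + 1e-300)

        def bw(g):
            if self.requires_grad:
                gz = p.copy()
                gz[np.arange(n), labels] -= 1.0
                self._accumulate(g * gz / n)

        return Tensor(nll.mean(), parents=(self,), backward=bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
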