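"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` records the
operation that produced it and a closure that routes upstream gradients to
its parents.  Only the operations needed by the EEG models in this package
are provided (dense/convolutional layers, normalizations, attention
arithmetic, softmax cross-entropy).  Everything runs in float64 so that
training is bit-reproducible for a fixed seed in single-threaded numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(out)/d(out)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------ elementwise
    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    # --------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def flip(self, axis: int) -> "Tensor":
        """Reverse along ``axis`` (time reversal for the backward branch)."""

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        return self._make(np.flip(self.data, axis=axis), (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)

        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, gp in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(gp)

        out = Tensor(out_data)
        out.requires_grad = any(t.requires_grad for t in tensors)
        if out.requires_grad:
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    # --------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ fused layers
    def conv1d(self, weight: "Tensor", bias: "Tensor" | None = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Cross-correlation along the last axis.

        ``self``: (N, C_in, L); ``weight``: (C_out, C_in, k); returns
        (N, C_out, L_out) with L_out = (L + 2*padding - k)//stride + 1.
        Implemented by an im2col view + one einsum, with the exact adjoint
        (col2im scatter) in the backward pass.
        """
        x = self.data
        n, c_in, length = x.shape
        c_out, c_in_w, k = weight.data.shape
        if c_in_w != c_in:
            raise ValueError(f"conv1d channel mismatch: input {c_in}, weight {c_in_w}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        else:
            xp = x
        l_pad = xp.shape[-1]
        l_out = (l_pad - k) // stride + 1
        if l_out <= 0:
            raise ValueError(f"conv1d: length {length} too short for kernel {k}")
        s0, s1, s2 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c_in, l_out, k), strides=(s0, s1, s2 * stride, s2)
        )
        out_data = np.einsum("nclk,ock->nol", cols, weight.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        def backward(g):
            if weight.requires_grad:
                gw = np.einsum("nol,nclk->ock", g, cols, optimize=True)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gcols = np.einsum("nol,ock->nclk", g, weight.data, optimize=True)
                gx = np.zeros_like(xp)
                for j in range(k):  # scatter-add the k taps
                    gx[:, :, j : j + stride * l_out : stride] += gcols[:, :, :, j]
                if padding:
                    gx = gx[:, :, padding:-padding]
                self._accum(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        return self._make(p, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis with learnable affine."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gamma.data + beta.data
        d = self.data.shape[-1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(
                    _unbroadcast(g * xhat, gamma.data.shape)
                )
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if self.requires_grad:
                gx = g * gamma.data
                gsum = gx.sum(axis=-1, keepdims=True)
                gdot = (gx * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv * (gx - gsum / d - xhat * gdot / d))

        return self._make(out_data, (self, gamma, beta), backward)

    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy; ``self`` is (N, K) logits."""
        labels = np.asarray(labels, dtype=np.intp)
        n = self.data.shape[0]
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - logz
        loss = -logp[np.arange(n), labels].mean()

        def backward(g):
            if self.requires_grad:
                p = np.exp(logp)
                p[np.arange(n), labels] -= 1.0
                self._accum(g * p / n)

        return self._make(loss, (self,), backward)


class Parameter(Tensor):
    """A tensor that is updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
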