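"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the sequence classifier needs:
broadcast-aware arithmetic, matmul, pointwise nonlinearities, reductions,
reshaping/indexing, concatenation, and an im2col-based 2D convolution.
Gradients are accumulated by a topological backward sweep, as in any
define-by-run framework.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv2d_patches", "no_grad"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(
                np.broadcast_to(grad, self.data.shape), dtype=np.float64
            )
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order (graphs can be thousands of nodes deep)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        del stack_
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visiting.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------- arithmetic
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            if self.requires_grad:
                self._accum(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-grad * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        # supports 2D @ 2D and batched ND @ 2D (the conv patches case)
        other = self._coerce(other)
        if other.ndim != 2:
            raise ValueError("matmul rhs must be 2D")
        out_data = self.data @ other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                lhs = self.data.reshape(-1, self.shape[-1])
                other._accum(lhs.T @ grad.reshape(-1, grad.shape[-1]))

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad / self.data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * mask)

        return self._make(out_data, (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes through only where un-clipped."""
        mask = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * mask)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            if not self.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_(self, axis: int, keepdims: bool = False):
        """Max reduction along one axis (ties send gradient to the first)."""
        out_data = self.data.max(axis=axis, keepdims=True)
        idx = self.data.argmax(axis=axis)

        def backward(grad):
            if not self.requires_grad:
                return
            g = grad if keepdims else np.expand_dims(grad, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)

        return self._make(
            out_data if keepdims else out_data.squeeze(axis), (self,), backward
        )

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(grad):
            if self.requires_grad:
                dot = (grad * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (grad - dot))

        return self._make(out_data, (self,), backward)

    # ----------------------------------------------------------- shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def backward(grad):
            if self.requires_grad:
                self._accum(grad.reshape(in_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        out_data = self.data[key]
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key)
        )

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:
                    full[key] += grad
                else:
                    np.add.at(full, key, grad)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(grad, i, axis=axis))

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, Ho*Wo, C*k*k) patch matrix, plus output spatial size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of _im2col: scatter-add patch gradients back to image grid."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    grad_x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            grad_x[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride] += cols6[
                :, :, :, :, di, dj
            ]
    if pad:
        grad_x = grad_x[:, :, pad : pad + h, pad : pad + w]
    return grad_x


def conv2d_patches(x: Tensor, k: int, stride: int, pad: int):
    """Differentiable im2col; follow with a matmul against the kernel matrix.

    Returns (patches, h_out, w_out) with patches of shape (N, Ho*Wo, C*k*k).
    """
    cols, ho, wo = _im2col(x.data, k, stride, pad)

    def backward(grad):
        if x.requires_grad:
            x._accum(_col2im(grad, x.shape, k, stride, pad))

    out = Tensor(cols)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out, ho, wo
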