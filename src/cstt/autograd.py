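"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The activity-recognition model in :mod:`cstt.model` is trained on a single
CPU without a deep-learning framework, so this module provides the small set
of differentiable primitives the architecture needs: broadcast-aware
arithmetic, (batched) matrix multiplication, the usual pointwise
nonlinearities, reductions, shape manipulation, a 2-D convolution, and an
Adam optimizer with decoupled weight decay.

Gradients are accumulated by reverse topological traversal.  Every primitive
is checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were added or broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.shape != self.data.shape:
                grad = np.broadcast_to(grad, self.data.shape)
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def _accumulate_owned(self, grad: np.ndarray) -> None:
        """Accumulate a gradient array the caller guarantees is freshly
        allocated and not aliased; on first touch it is adopted without a
        copy."""
        if self.grad is None and grad.shape == self.data.shape \
                and grad.dtype == self.data.dtype:
            self.grad = grad
        else:
            self._accumulate(grad)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # the graph is spent: dismantle it so refcounting frees every
        # intermediate immediately (leaf gradients are kept)
        for node in topo:
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate_owned(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate_owned(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate_owned(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        if other.data.ndim == 2 and self.data.ndim > 2:
            # stacked @ weight-matrix: run one large GEMM instead of a loop
            lead = self.data.shape[:-1]
            a2d = self.data.reshape(-1, self.data.shape[-1])
            out = Tensor((a2d @ other.data).reshape(lead + (other.data.shape[-1],)),
                         _parents=(self, other))

            def bw(g):
                g2d = g.reshape(-1, g.shape[-1])
                if self.requires_grad:
                    self._accumulate_owned((g2d @ other.data.T).reshape(self.shape))
                if other.requires_grad:
                    other._accumulate_owned(a2d.T @ g2d)

            out._backward = bw
            return out
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate_owned(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate_owned(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- pointwise --------------------------------------------------------

    def exp(self):
        y = np.exp(self.data)  # captured as a bare array: no reference cycle
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate_owned(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate_owned(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate_owned(
            g * (1.0 - y ** 2)
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate_owned(
            g * (self.data > 0.0)
        )
        return out

    # -- reductions and shape ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    # -- composites -------------------------------------------------------

    def softmax(self, axis: int = -1):
        """Numerically stable softmax; the max-shift is treated as a constant."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def layer_norm(self, eps: float = 1e-5):
        """Normalize the last axis to zero mean, unit variance."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + eps) ** -0.5


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bw
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2-D convolution, stride 1, same (zero) padding, odd square kernel.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, k, k); ``bias``: (C_out,).
    Implemented as a sum of k*k shifted slice products so both directions of
    the backward pass are plain vectorized array ops.
    """
    b, c_in, h, w = x.shape
    c_out, c_in_w, k, k2 = weight.shape
    if c_in != c_in_w or k != k2 or k % 2 != 1:
        raise ValueError("conv2d expects matching channels and an odd square kernel")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    out_data = np.zeros((b, c_out, h, w), dtype=x.data.dtype)
    for dy in range(k):
        for dx in range(k):
            # accumulate per input channel with broadcast multiplies; kernels
            # here are tiny, so this beats im2col's memory traffic
            for ci in range(c_in):
                patch = xp[:, ci, dy:dy + h, dx:dx + w]  # (B, H, W)
                w_tap = weight.data[:, ci, dy, dx]  # (C_out,)
                out_data += patch[:, None] * w_tap[None, :, None, None]
    if bias is not None:
        out_data += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for dy in range(k):
                for dx in range(k):
                    for ci in range(c_in):
                        patch = xp[:, ci, dy:dy + h, dx:dx + w]
                        gw[:, ci, dy, dx] = (g * patch[:, None]).sum(axis=(0, 2, 3))
            weight._accumulate_owned(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros((b, c_in, h + 2 * p, w + 2 * p), dtype=g.dtype)
            for dy in range(k):
                for dx in range(k):
                    for ci in range(c_in):
                        w_tap = weight.data[:, ci, dy, dx]
                        gxp[:, ci, dy:dy + h, dx:dx + w] += (
                            g * w_tap[None, :, None, None]
                        ).sum(axis=1)
            x._accumulate_owned(np.ascontiguousarray(gxp[:, :, p:p + h, p:p + w]))

    out._backward = bw
    return out


class AdamW:
    """Adam with decoupled weight decay on a flat list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)
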