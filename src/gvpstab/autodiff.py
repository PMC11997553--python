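"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the geometric graph network in this
package: a :class:`Tensor` wrapping an ndarray, a closed set of
differentiable operations (broadcast arithmetic, batched matmul, channel
mixing for stacked 3-vectors, reductions, segment means for message
aggregation, concatenation, elementwise nonlinearities), and backward
accumulation by topological sort.  Gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return self._op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return self._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return self._op(np.matmul(self.data, other.data), (self, other), backward)

    def pow_const(self, exponent: float):
        def backward(g, a=self, e=exponent):
            a._accum(g * e * a.data ** (e - 1))

        return self._op(self.data ** exponent, (self,), backward)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self, s=old):
            a._accum(g.reshape(s))

        return self._op(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        def backward(g, a=self):
            a._accum(np.swapaxes(g, ax1, ax2))

        return self._op(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Gather rows along axis 0 (differentiable scatter-add backward)."""
        indices = np.asarray(indices, dtype=np.int64)

        def backward(g, a=self, idx=indices):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accum(buf)

        return self._op(self.data[indices], (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._op(self.data.sum(axis=axis, keepdims=keepdims),
                        (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._accum(g * m)

        return self._op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return self._op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * o)

        return self._op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return self._op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g / (2.0 * o))

        return self._op(out_data, (self,), backward)

    # -- backward ------------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


# ---------------------------------------------------------------------------
# Free functions

def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, off=offsets):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g, ts=tensors):
        for i, t in enumerate(ts):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._op(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )


def vecmat(weight: Tensor, vectors: Tensor) -> Tensor:
    """Mix stacked 3-vector channels: (h, v) x (n, v, 3) -> (n, h, 3)."""

    def backward(g, w=weight, V=vectors):
        w._accum(np.einsum("nhc,nvc->hv", g, V.data))
        V._accum(np.einsum("hv,nhc->nvc", w.data, g))

    return Tensor._op(
        np.einsum("hv,nvc->nhc", weight.data, vectors.data),
        (weight, vectors), backward,
    )


def vector_norm(v: Tensor, eps: float = 1e-8) -> Tensor:
    """Norms over the trailing 3-axis: (n, h, 3) -> (n, h); smooth at 0."""
    return ((v * v).sum(axis=-1) + eps).sqrt()


def segment_mean(values: Tensor, segment_ids: np.ndarray,
                 num_segments: int) -> Tensor:
    """Mean of rows grouped by segment id; empty segments give zeros."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    safe = np.maximum(counts, 1.0)
    out_shape = (num_segments,) + values.data.shape[1:]
    sums = np.zeros(out_shape)
    np.add.at(sums, segment_ids, values.data)
    scale = safe.reshape((-1,) + (1,) * (values.data.ndim - 1))

    def backward(g, v=values, ids=segment_ids, s=scale):
        v._accum((g / s)[ids])

    return Tensor._op(sums / scale, (values,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - np.max(t.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(t: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def binary_cross_entropy(probs: Tensor, labels: np.ndarray,
                         eps: float = 1e-7) -> Tensor:
    """Mean BCE of predicted probabilities against 0/1 labels."""
    y = np.asarray(labels, dtype=np.float64)
    p = probs * (1 - 2 * eps) + eps   # clamp away from {0, 1}
    loss = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    return loss.mean()


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with optional L2 weight decay (coupled, as in classic Adam)."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
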