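"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the model needs: broadcast arithmetic,
matrix products, elementwise nonlinearities, reductions, slicing/concat,
and the dense linear-algebra primitives (matrix inverse, log-determinant)
required by the sparse-GP evidence bound.  Gradients are accumulated by
topological traversal of the recorded tape.

All arrays are float64; shapes follow numpy broadcasting rules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be a view into another node's buffer
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack_ = [self]
        # iterative DFS (graphs can be deep for long loops)
        visit_stack = [(self, False)]
        while visit_stack:
            node, processed = visit_stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit_stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visit_stack.append((p, False))
        del stack_
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _op(np.add(self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _op(np.multiply(self.data, other.data), (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _op(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, k: float):
        out = _op(self.data**k, (self,))

        def bw(g):
            self._accumulate(g * k * self.data ** (k - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _op(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                if other.data.ndim == 1:
                    if self.data.ndim == 1:
                        self._accumulate(g * other.data)
                    else:
                        # out[..., i] = sum_j self[..., i, j] * other[j]
                        self._accumulate(np.expand_dims(g, -1) * other.data)
                else:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad or other._parents:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g) if other.data.ndim == 2 else g * self.data)
                elif other.data.ndim == 1:
                    prod = self.data * np.expand_dims(g, -1)
                    other._accumulate(prod.reshape(-1, self.data.shape[-1]).sum(axis=0))
                else:
                    other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bw
        return out

    # ---- elementwise ----------------------------------------------------
    def exp(self):
        out = _op(np.exp(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _op(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = _op(np.sqrt(self.data), (self,))
        out._backward = lambda g: self._accumulate(0.5 * g / out.data)
        return out

    def tanh(self):
        out = _op(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = _op(_sigmoid(self.data), (self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = _op(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def softplus(self):
        # log(1 + e^x), overflow-safe
        out = _op(np.logaddexp(0.0, self.data), (self,))
        out._backward = lambda g: self._accumulate(g * _sigmoid(self.data))
        return out

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _op(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = _op(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = _op(self.data.T, (self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    def __getitem__(self, idx):
        out = _op(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # ---- dense linear algebra -------------------------------------------
    def inv(self):
        """Matrix inverse; grad dA = -A^{-T} G A^{-T}."""
        out = _op(np.linalg.inv(self.data), (self,))
        out._backward = lambda g: self._accumulate(-out.data.T @ g @ out.data.T)
        return out

    def logdet(self):
        """log|det A| for (symmetric) positive-definite A; grad = A^{-T}."""
        sign, ld = np.linalg.slogdet(self.data)
        out = _op(ld, (self,))
        inv = np.linalg.inv(self.data)
        out._backward = lambda g: self._accumulate(g * inv.T)
        return out

    def diag_part(self):
        out = _op(np.diagonal(self.data).copy(), (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.fill_diagonal(full, g)
            self._accumulate(full)

        out._backward = bw
        return out

    def diag_embed(self):
        out = _op(np.diag(self.data), (self,))
        out._backward = lambda g: self._accumulate(np.diagonal(g).copy())
        return out

    def softmax(self, axis=-1):
        # shift by a detached max (softmax is shift-invariant, grads unchanged)
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.grad is not None else 'no'})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _op(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def tensor(data, requires_grad: bool = False, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=requires_grad, name=name)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _op(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad or t._parents:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
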