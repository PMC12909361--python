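"""Reverse-mode automatic differentiation over numpy arrays.

The training objective of a distributional PINN is a scalar built from a
neural-network forward pass, log-normal moment algebra, reparameterised
multivariate sampling and ODE right-hand-side evaluations.  Gradients with
respect to every trainable quantity (network weights, population-distribution
parameters, residual noise, correlations) are obtained by taping these
operations and running the chain rule backwards through the tape.

Only the primitives the package actually uses are implemented.  Broadcasting
follows numpy semantics; gradients of broadcast operands are summed back to
the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes where original dim was 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a value, a gradient slot, and a
    backward rule closing over the parents."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    # make numpy defer to the reflected operators instead of trying to
    # broadcast a Tensor elementwise
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack_ = [self]
        # iterative post-order topological sort
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * p * self.data ** (p - 1)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                          self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                           other.data.shape)

        out._backward = bwd
        return out

    # -- elementwise functions ---------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * val

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = bwd
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * 0.5 / val

        out._backward = bwd
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - val ** 2)

        out._backward = bwd
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * val * (1.0 - val)

        out._backward = bwd
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, (self,))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * sig

        out._backward = bwd
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))
        # basic indexing yields disjoint views, so in-place += is safe and
        # much faster than ufunc.at (needed only for fancy indices)
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis
                    for p in parts)

        def bwd(g):
            if self.requires_grad:
                if basic:
                    self.grad[idx] += g
                else:
                    np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t.grad += g[tuple(sl)]

    out._backward = bwd
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += np.take(g, i, axis=axis)

    out._backward = bwd
    return out


class Adam:
    """Adam optimiser with global gradient-norm clipping and exponential
    learning-rate decay (a fixed factor applied every `decay_every` steps)."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8,
                 clip_norm=10.0, decay_factor=0.99, decay_every=1000):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if self.decay_factor is None or self.decay_every is None:
            return self.lr
        return self.lr * self.decay_factor ** (self.t // self.decay_every)

    def clip_gradients(self) -> float:
        """Scale all gradients so the global Euclidean norm is <= clip_norm.
        Returns the pre-clip norm.

        Parameters that did not participate in the loss (grad is None)
        are treated as having zero gradient."""
        for p in self.params:
            if p.grad is None:
                p.grad = np.zeros_like(p.data)
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
        if self.clip_norm is not None and total > self.clip_norm and total > 0:
            scale = self.clip_norm / total
            for p in self.params:
                p.grad *= scale
        return total

    def step(self):
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
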