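"""Minimal vectorized reverse-mode automatic differentiation.

The networks in this package are four tiny dense stacks (a few hundred
parameters each), so instead of depending on a deep-learning framework the
package carries a compact numpy tape.  Only the operations the training
losses need are implemented: affine layers, leaky rectifier, sigmoid,
elementwise arithmetic, absolute value, square root, reductions and
concatenation.  Everything is float64 and single-threaded, which makes
training runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that routes its gradient backwards."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    # defer mixed ndarray/Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

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

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def leaky_relu(self, slope: float) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.where(mask, 1.0, slope)
        )
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * s * (1.0 - s)
        )
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.data
        )
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), (self,))
        # subgradient 0 at the kink
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * np.sign(self.data)
        )
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * 0.5 / r
        )
        return out

    def softplus(self) -> "Tensor":
        # log(1 + exp(x)) computed without overflow; gradient is sigmoid(x)
        out = Tensor(np.logaddexp(0.0, self.data), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / (1.0 + np.exp(-self.data))
        )
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * mask
        )
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                self._accumulate(
                    np.broadcast_to(np.expand_dims(g, axis), self.data.shape)
                )

        out._backward = bwd
        return out

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused dense layer ``x @ W + b`` (one tape node instead of two)."""
    out = Tensor(x.data @ W.data + b.data, (x, W, b))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g @ W.data.T)
        if W.requires_grad:
            W._accumulate(x.data.T @ g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors.

    beta1 defaults to 0.5, the customary choice for adversarial training.
    The learning rate is a plain attribute so schedules can mutate it
    between steps.
    """

    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
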