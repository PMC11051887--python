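"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the network needs: dense affine maps,
LeakyReLU/ReLU/sigmoid nonlinearities, row gather / segment scatter (for
message passing over edge lists), concatenation, dropout masking, and a
numerically stable binary cross-entropy on logits.  Gradients are accumulated
by topological traversal of the recorded tape.  Everything is float64 and
single-threaded, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """A node in the computation graph wrapping an ndarray.

    ``requires_grad`` leaves propagate gradients into ``.grad``; interior
    nodes carry a backward closure and references to their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        track = any(p.requires_grad or p._backward is not None for p in parents)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # defensive copy: g may be a view
        else:
            self.grad = self.grad + g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Run backpropagation from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if seed is None else np.asarray(seed)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                pg = _reduce_to(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        return self._result(
            self.data + other.data,
            (self, other),
            lambda g: (g, g),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = self._wrap(other)
        return self._result(
            self.data - other.data,
            (self, other),
            lambda g: (g, -g),
        )

    def __mul__(self, other):
        other = self._wrap(other)
        return self._result(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self._result(-self.data, (self,), lambda g: (-g,))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1:
                ga = g @ b.T
            else:
                ga = g @ b.T
            gb = a.T @ g if a.ndim > 1 else np.outer(a, g)
            return ga, gb

        return self._result(a @ b, (self, other), backward)

    def __matmul__(self, other):
        return self.matmul(other)

    def sum(self) -> "Tensor":
        return self._result(
            self.data.sum(),
            (self,),
            lambda g: (np.broadcast_to(g, self.data.shape),),
        )

    def mean(self) -> "Tensor":
        n = self.data.size
        return self._result(
            self.data.mean(),
            (self,),
            lambda g: (np.broadcast_to(g / n, self.data.shape),),
        )

    # -- nonlinearities -----------------------------------------------------

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        return self._result(self.data * mask, (self,), lambda g: (g * mask,))

    def relu(self) -> "Tensor":
        mask = (self.data > 0).astype(np.float64)
        return self._result(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out = _stable_sigmoid(self.data)
        return self._result(out, (self,), lambda g: (g * out * (1.0 - out),))

    # -- structural ops -----------------------------------------------------

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """out[r] = self[idx[r]]; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)
        n = self.data.shape[0]

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return (acc,)

        del n
        return self._result(self.data[idx], (self,), backward)

    def segment_sum(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows of self into ``n_segments`` buckets given by ``seg``."""
        seg = np.asarray(seg, dtype=np.intp)
        shape = (n_segments,) + self.data.shape[1:]
        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, seg, self.data)
        return self._result(out, (self,), lambda g: (g[seg],))

    def concat(self, other: "Tensor") -> "Tensor":
        """Concatenate along the last axis."""
        other = self._wrap(other)
        k = self.data.shape[-1]
        return self._result(
            np.concatenate([self.data, other.data], axis=-1),
            (self, other),
            lambda g: (g[..., :k], g[..., k:]),
        )

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return self._result(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return self._result(out, (self,), lambda g: (g * out,))

    def __truediv__(self, other):
        other = self._wrap(other)
        return self._result(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / other.data**2),
        )


def _reduce_to(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-collapse broadcast axes so ``g`` matches ``shape``."""
    g = np.asarray(g, dtype=np.float64)
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|)); the gradient wrt z is
    sigmoid(z) - y, divided by n for the mean.
    """
    z = logits.data
    y = np.asarray(labels, dtype=np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        return (g * (_stable_sigmoid(z) - y) / n,)

    return Tensor._result(per.mean(), (logits,), backward)


class Adam:
    """Adam optimizer over a dict of parameter Tensors (in-place updates)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
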