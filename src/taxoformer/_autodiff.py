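"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoder, its classification heads and the training loop are written
against this small tape: a ``Tensor`` wraps an ndarray, records its parents
and a backward closure, and ``backward()`` walks the tape in reverse
topological order.  Only the operations the model needs are provided
(broadcast add/mul, batched matmul, ReLU, softmax, layer norm, embedding
gather, reductions, dropout, cross-entropy).

Everything runs in float32; gradients accumulate in float32 as well.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        # float64 passes through (analysis/oracle use); everything else is float32
        arr = np.asarray(data)
        self.data = arr if arr.dtype == np.float64 else np.asarray(arr, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()
        self.name = name
        self._grad_owned = False

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        # store a reference on first touch (may be a view shared with another
        # consumer); allocate only if a second gradient stream arrives
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this (typically scalar) tensor through the tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data)
        _wire(out, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other)
            _wire(out, (self,))
            out._backward = lambda g: self._accumulate(g * other)
            return out
        other = _as_tensor(other)
        out = Tensor(self.data * other.data)
        _wire(out, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data))
        _wire(out, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0))
        _wire(out, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        _wire(out, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes))
        inv = np.argsort(axes)
        _wire(out, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        _wire(out, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx])
        _wire(out, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _wire(out: Tensor, parents: Tuple[Tensor, ...]) -> None:
    track = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = track
    out.requires_grad = bool(track)


class Parameter(Tensor):
    """Trainable tensor; optionally carries sparse-row bookkeeping."""

    __slots__ = ("touched_rows",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)
        self.touched_rows: Optional[np.ndarray] = None


def softmax(x: Tensor, axis: int = -1, has_neg_inf: bool = True) -> Tensor:
    """Row softmax; tolerates -inf entries (they get exactly zero weight)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    if has_neg_inf:
        m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y)
    _wire(out, (x,))

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last (feature) dimension."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data)
    _wire(out, (x, gain, bias))
    d = x.data.shape[-1]

    def bw(g):
        if gain.requires_grad or gain._parents:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad or bias._parents:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if x.requires_grad or x._parents:
            gx = g * gain.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(term * inv)

    out._backward = bw
    return out


def embedding(table: Parameter, ids: np.ndarray) -> Tensor:
    """Gather rows of ``table`` by integer ``ids`` (any leading shape)."""
    out = Tensor(table.data[ids])
    _wire(out, (table,))

    def bw(g):
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
            table._grad_owned = True
        np.add.at(table.grad, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        rows = np.unique(ids)
        if table.touched_rows is None:
            table.touched_rows = rows
        else:
            table.touched_rows = np.union1d(table.touched_rows, rows)

    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(DTYPE) / DTYPE(1.0 - rate)
    out = Tensor(x.data * keep)
    _wire(out, (x,))
    out._backward = lambda g: x._accumulate(g * keep)
    return out


def cross_entropy(
    logits: Tensor,
    labels: np.ndarray,
    sample_weights: Optional[np.ndarray] = None,
    reduction: str = "mean",
) -> Tensor:
    """Weighted softmax cross-entropy from unnormalised scores.

    Stabilised via log-sum-exp; ``sample_weights`` multiplies each example's
    loss (the class-imbalance weights w_{i, y_i}).
    """
    z = logits.data
    m = z.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))
    logp = z - lse
    B = z.shape[0]
    picked = logp[np.arange(B), labels]
    w = np.ones(B, dtype=DTYPE) if sample_weights is None else np.asarray(sample_weights, dtype=DTYPE)
    losses = -picked * w
    if reduction == "mean":
        val = losses.mean()
        scale = w / B
    elif reduction == "sum":
        val = losses.sum()
        scale = w
    else:
        raise ValueError("reduction must be 'mean' or 'sum'")
    out = Tensor(val)
    _wire(out, (logits,))
    p = np.exp(logp)

    def bw(g):
        grad = p.copy()
        grad[np.arange(B), labels] -= 1.0
        grad *= (scale * float(g))[:, None] if np.ndim(g) == 0 else (scale * g)[:, None]
        logits._accumulate(grad)

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    _wire(out, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accumulate(piece)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer; optionally lazy (sparse) updates for embedding tables.

    With ``sparse=True`` a parameter whose backward recorded touched rows has
    only those rows' moments and values updated in a step, mirroring
    sparse-gradient embedding training.
    """

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 0.01,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        sparse: bool = False,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.sparse = sparse
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
            p._grad_owned = False
            p.touched_rows = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.sparse and p.touched_rows is not None:
                rows = p.touched_rows
                g = p.grad[rows]
                self.m[i][rows] = self.b1 * self.m[i][rows] + (1 - self.b1) * g
                self.v[i][rows] = self.b2 * self.v[i][rows] + (1 - self.b2) * g * g
                mhat = self.m[i][rows] / b1t
                vhat = self.v[i][rows] / b2t
                p.data[rows] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            else:
                g = p.grad
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / b1t
                vhat = self.v[i] / b2t
                p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "lr": self.lr,
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
        self.lr = state["lr"]
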