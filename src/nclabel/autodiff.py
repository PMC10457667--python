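"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models trained in this package are small (a linear or shallow-MLP
encoder plus an affine classifier), so a compact tape-based engine is all
that is needed: every operation builds a node closing over its local
vector-Jacobian product, and :meth:`Tensor.backward` runs the tape in
reverse topological order.  Only the operations required by the training
losses are implemented.  Gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat_rows", "logsumexp", "matmul", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _vjps: Sequence[Callable[[np.ndarray], np.ndarray]] = (),
    ) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._vjps = tuple(_vjps)

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        return Tensor(
            self.value + other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.value, _parents=(self,), _vjps=(lambda g: -g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        return Tensor(
            self.value * other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g * other.value, self.shape),
                lambda g: _unbroadcast(g * self.value, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return Tensor(
            self.value / other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: _unbroadcast(g / other.value, self.shape),
                lambda g: _unbroadcast(-g * self.value / other.value**2, other.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.value**exponent,
            _parents=(self,),
            _vjps=(lambda g: g * exponent * self.value ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        return Tensor(
            self.value @ other.value,
            _parents=(self, other),
            _vjps=(
                lambda g: g @ other.value.T,
                lambda g: self.value.T @ g,
            ),
        )

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        out = np.exp(self.value)
        return Tensor(out, _parents=(self,), _vjps=(lambda g: g * out,))

    def log(self) -> "Tensor":
        return Tensor(np.log(self.value), _parents=(self,), _vjps=(lambda g: g / self.value,))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.value)
        return Tensor(out, _parents=(self,), _vjps=(lambda g: g * 0.5 / out,))

    def abs(self) -> "Tensor":
        # subgradient 0 at 0
        return Tensor(
            np.abs(self.value), _parents=(self,), _vjps=(lambda g: g * np.sign(self.value),)
        )

    def relu(self) -> "Tensor":
        mask = self.value > 0
        return Tensor(
            np.where(mask, self.value, 0.0), _parents=(self,), _vjps=(lambda g: g * mask,)
        )

    # -------------------------------------------------------------- reshaping
    @property
    def T(self) -> "Tensor":
        return Tensor(self.value.T, _parents=(self,), _vjps=(lambda g: g.T,))

    def reshape(self, *shape) -> "Tensor":
        return Tensor(
            self.value.reshape(*shape),
            _parents=(self,),
            _vjps=(lambda g: g.reshape(self.shape),),
        )

    def take_rows(self, rows: np.ndarray, cols: np.ndarray) -> "Tensor":
        """Fancy-index a 2-D tensor at paired (row, col) positions."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)

        def vjp(g: np.ndarray) -> np.ndarray:
            out = np.zeros(self.shape)
            np.add.at(out, (rows, cols), g)
            return out

        return Tensor(self.value[rows, cols], _parents=(self,), _vjps=(vjp,))

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def vjp(g: np.ndarray) -> np.ndarray:
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            g_expanded = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g_expanded, self.shape).copy()

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,), _vjps=(vjp,))

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate d(self)/d(leaf) into ``.grad`` of every reachable tensor."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.value)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                contribution = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contribution
                else:
                    grads[id(parent)] = contribution
            if node.requires_grad and node._parents:
                # interior nodes keep no gradient; leaves accumulated above
                pass


# ------------------------------------------------------------------ functions
def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor._lift(a) @ b


def relu(x: Tensor) -> Tensor:
    return Tensor._lift(x).relu()


def concat_rows(parts: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    parts = [Tensor._lift(p) for p in parts]
    sizes = [p.shape[0] for p in parts]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    vjps = []
    for i, p in enumerate(parts):
        lo, hi = int(offsets[i]), int(offsets[i + 1])
        vjps.append(lambda g, lo=lo, hi=hi: g[lo:hi])
    return Tensor(np.concatenate([p.value for p in parts], axis=0), _parents=parts, _vjps=vjps)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along one axis."""
    shift = np.max(x.value, axis=axis, keepdims=True)
    shifted = x - Tensor(shift)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
    if not keepdims:
        out = out.reshape(np.squeeze(out.value, axis=axis).shape)
    return out
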