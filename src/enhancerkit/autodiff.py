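"""A compact reverse-mode automatic differentiation engine on NumPy arrays.

Purpose-built for the adversarial sequence generator: it supports exactly
the operations its two networks need (dense and 1-D convolution layers,
ReLU/ELU/softmax activations, reductions, square roots) and — crucially —
*higher-order* differentiation: every backward rule is itself expressed in
terms of these differentiable operations, so gradients of gradients (as
required by the Wasserstein gradient penalty) come out of the same
machinery.

The design is deliberately simple: a :class:`Tensor` records its parents and
a vector-Jacobian-product closure; :func:`grad` walks the graph in reverse
topological order building new Tensors, which may be differentiated again.
"""

from __future__ import annotations

from typing import Callable, Sequence as TypingSequence

import numpy as np

__all__ = ["Tensor", "grad", "relu", "elu", "softmax", "conv1d", "Adam"]


class Tensor:
    """An array node in a differentiable computation graph."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        vjp: Callable[["Tensor"], tuple["Tensor | None", ...]] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjp = vjp
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            vjp=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            vjp=lambda g: (
                _unbroadcast(g * other, self.shape),
                _unbroadcast(g * self, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        return Tensor(
            self.data**p,
            parents=(self,),
            vjp=lambda g: (g * (p * self ** (p - 1.0)),),
        )

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        out.vjp = lambda g: (g * out,)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.shape
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            vjp=lambda g: (g.reshape(*old),),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor(self.data.T, parents=(self,), vjp=lambda g: (g.T,))

    def broadcast_to(self, shape) -> "Tensor":
        old = self.shape
        return Tensor(
            np.broadcast_to(self.data, shape),
            parents=(self,),
            vjp=lambda g: (_unbroadcast(g, old),),
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def vjp(g: "Tensor"):
            if axis is None:
                return (g.reshape(*([1] * len(shape))).broadcast_to(shape),)
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(a % len(shape) for a in axes)
            if not keepdims:
                kept = [1 if i in axes else s for i, s in enumerate(shape)]
                g = g.reshape(*kept)
            return (g.broadcast_to(shape),)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), vjp=vjp
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra --------------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            vjp=lambda g: (g @ other.T, self.T @ g),
        )

    # -- padding / windowing (linear ops used by conv1d) ----------------------

    def pad_axis1(self, before: int, after: int) -> "Tensor":
        """Zero-pad along axis 1 of an (N, L, C) tensor."""
        L = self.shape[1]
        return Tensor(
            np.pad(self.data, ((0, 0), (before, after), (0, 0))),
            parents=(self,),
            vjp=lambda g: (g.slice_axis1(before, before + L),),
        )

    def slice_axis1(self, start: int, stop: int) -> "Tensor":
        L = self.shape[1]
        return Tensor(
            self.data[:, start:stop],
            parents=(self,),
            vjp=lambda g: (g.pad_axis1(start, L - stop),),
        )

    def take_windows(self, idx: np.ndarray) -> "Tensor":
        """Gather sliding windows: (N, L, C) indexed by (O, K) -> (N, O, K, C)."""
        L = self.shape[1]
        return Tensor(
            self.data[:, idx, :],
            parents=(self,),
            vjp=lambda g: (g.scatter_windows(idx, L),),
        )

    def scatter_windows(self, idx: np.ndarray, L: int) -> "Tensor":
        """Adjoint of take_windows: (N, O, K, C) scattered back to (N, L, C)."""
        n, _, _, c = self.shape
        out = np.zeros((n, L, c))
        np.add.at(out, (slice(None), idx, slice(None)), self.data)
        return Tensor(out, parents=(self,), vjp=lambda g: (g.take_windows(idx),))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a gradient back to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    extra = len(g.shape) - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# activations


def relu(x: Tensor) -> Tensor:
    mask = Tensor((x.data > 0).astype(np.float64))
    return Tensor(x.data * mask.data, parents=(x,), vjp=lambda g: (g * mask,))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = Tensor((x.data > 0).astype(np.float64))
    neg = Tensor(1.0) - pos
    expx = x.exp()
    out_data = np.where(x.data > 0, x.data, alpha * (np.exp(x.data) - 1.0))
    # gradient flows directly for x > 0 and through expx (alpha * e^x) otherwise,
    # which keeps the rule differentiable for higher-order use
    return Tensor(out_data, parents=(x, expx), vjp=lambda g: (g * pos, g * (neg * alpha)))


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis (numerically shifted by a constant max)."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift.broadcast_to(x.shape)).exp()
    return e / e.sum(axis=-1, keepdims=True).broadcast_to(x.shape)


# ---------------------------------------------------------------------------
# convolution


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, kernel: int) -> Tensor:
    """Length-preserving ("same"-padded) 1-D convolution.

    ``x`` is (N, L, C_in); ``weight`` is (kernel * C_in, C_out); ``bias``
    (C_out,).  Returns (N, L, C_out).
    """
    n, L, c_in = x.shape
    c_out = weight.shape[1]
    before = (kernel - 1) // 2
    after = kernel - 1 - before
    xp = x.pad_axis1(before, after)
    idx = np.arange(L)[:, None] + np.arange(kernel)[None, :]
    win = xp.take_windows(idx)  # (N, L, K, C_in)
    flat = win.reshape(n * L, kernel * c_in)
    out = flat @ weight
    return out.reshape(n, L, c_out) + bias.reshape(1, 1, c_out).broadcast_to(
        (n, L, c_out)
    )


# ---------------------------------------------------------------------------
# differentiation


def grad(
    output: Tensor,
    inputs: TypingSequence[Tensor],
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    The returned tensors are themselves graph nodes, so they can be
    differentiated again (double backprop).
    """
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad of a non-scalar output needs grad_output")
        grad_output = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(node: Tensor) -> None:
        stack = [(node, iter(node.parents))]
        if id(node) in seen or not node.requires_grad:
            return
        seen.add(id(node))
        while stack:
            current, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p.parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(current)
                stack.pop()

    visit(output)
    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None or node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg
    return [
        grads.get(id(inp), Tensor(np.zeros_like(inp.data))) for inp in inputs
    ]


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias correction."""

    def __init__(
        self,
        params: TypingSequence[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.5,
        beta2: float = 0.9,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads: TypingSequence[Tensor]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
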