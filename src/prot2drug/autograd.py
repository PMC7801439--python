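"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations an encoder-decoder transformer needs:
broadcasting add/mul, batched matmul, reshape/transpose, relu, softmax,
layer normalization, embedding lookup, dropout and a fused label-smoothed
cross-entropy.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` after a topological sort of the recorded graph.

Arrays keep whatever float dtype they are given; the transformer uses
float32 throughout, while gradient-checking tests may build float64 graphs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "relu",
    "softmax",
    "layer_norm",
    "embedding",
    "dropout",
    "cross_entropy",
]


class Tensor:
    """A node in the computation graph wrapping a NumPy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # zero out accumulated gradients on leaves reachable from here
    def zero_grad(self) -> None:
        self.grad = None


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _accumulate(t: Tensor, g: np.ndarray, own: bool = False) -> None:
    """Add ``g`` into ``t.grad``.

    ``own=True`` promises that ``g`` is a freshly allocated array not shared
    with any other node, so it can be adopted without copying.
    """
    if not t.requires_grad:
        return
    if t.grad is None:
        if own and g.dtype == t.data.dtype:
            t.grad = g
        else:
            t.grad = np.array(g, dtype=t.data.dtype)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> tuple[np.ndarray, bool]:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting).

    Returns (array, fresh) where ``fresh`` is True when a reduction actually
    allocated a new array.
    """
    fresh = False
    while g.ndim > len(shape):
        g = g.sum(axis=0)
        fresh = True
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
            fresh = True
    return g, fresh


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    req = a.requires_grad or b.requires_grad

    def backward(g):
        ga, fa = _unbroadcast(g, a.data.shape)
        _accumulate(a, ga, own=fa)
        gb, fb = _unbroadcast(g, b.data.shape)
        _accumulate(b, gb, own=fb)

    return Tensor(out_data, req, (a, b), backward if req else None)


def mul(a: Tensor, b) -> Tensor:
    """Elementwise product; ``b`` may be a Tensor or a plain scalar/array."""
    if not isinstance(b, Tensor):
        b = constant(np.asarray(b, dtype=a.data.dtype))
    out_data = a.data * b.data
    req = a.requires_grad or b.requires_grad

    def backward(g):
        if a.requires_grad:
            _accumulate(a, _unbroadcast(g * b.data, a.data.shape)[0], own=True)
        if b.requires_grad:
            _accumulate(b, _unbroadcast(g * a.data, b.data.shape)[0], own=True)

    return Tensor(out_data, req, (a, b), backward if req else None)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)
    req = a.requires_grad or b.requires_grad

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            _accumulate(a, _unbroadcast(ga, a.data.shape)[0], own=True)
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            _accumulate(b, _unbroadcast(gb, b.data.shape)[0], own=True)

    return Tensor(out_data, req, (a, b), backward if req else None)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(a.data.shape))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def transpose(a: Tensor, axes) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        _accumulate(a, np.transpose(g, inv))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def backward(g):
        _accumulate(a, g * (a.data > 0), own=True)

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def softmax(a: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, with an optional additive (mask) bias."""
    x = a.data + bias if bias is not None else a.data.copy()
    x -= x.max(axis=-1, keepdims=True)
    np.exp(x, out=x)
    x /= x.sum(axis=-1, keepdims=True)
    s = x

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        _accumulate(a, (g - dot) * s, own=True)

    return Tensor(s, a.requires_grad, (a,), backward if a.requires_grad else None)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine rescaling."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xhat = x.data - mu
    var = (xhat * xhat).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat *= inv
    out_data = xhat * gamma.data + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def backward(g):
        if gamma.requires_grad:
            _accumulate(gamma, _unbroadcast(g * xhat, gamma.data.shape)[0], own=True)
        if beta.requires_grad:
            gb, fb = _unbroadcast(g, beta.data.shape)
            _accumulate(beta, gb, own=fb)
        if x.requires_grad:
            n = x.data.shape[-1]
            gx = g * gamma.data
            gxh = gx * inv
            _accumulate(
                x,
                gxh
                - gxh.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True) * inv,
                own=True,
            )

    return Tensor(out_data, req, (x, gamma, beta), backward if req else None)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: output[..., :] = table[ids[...], :]."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            _accumulate(table, gt, own=True)

    return Tensor(out_data, table.requires_grad, (table,), backward if table.requires_grad else None)


def dropout(a: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout.  ``rng=None`` (inference) is the identity."""
    if rng is None or p <= 0.0:
        return a
    dt = a.data.dtype
    rdt = dt if dt == np.float32 else np.float64
    keep = (rng.random(a.data.shape, dtype=rdt) >= p).astype(dt)
    keep *= 1.0 / (1.0 - p)
    return mul(a, keep)


def cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    token_mask: np.ndarray,
    label_smoothing: float = 0.0,
) -> Tensor:
    """Mean label-smoothed cross-entropy over unmasked positions.

    ``logits`` has shape (..., V); ``targets`` integer ids and boolean
    ``token_mask`` share the leading shape.  Smoothed target distribution:
    (1 - eps) on the true class and eps/(V-1) spread over the rest.
    """
    v = logits.data.shape[-1]
    x = logits.data - logits.data.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(x).sum(axis=-1, keepdims=True))
    logp = x - logz
    mask = np.asarray(token_mask, dtype=bool)
    n = max(int(mask.sum()), 1)
    eps = label_smoothing
    true_lp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    loss_true = -(1.0 - eps) * true_lp
    loss_smooth = -(eps / (v - 1)) * (logp.sum(axis=-1) - true_lp)
    loss = ((loss_true + loss_smooth) * mask).sum() / n

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            target_dist = np.full_like(p, eps / (v - 1))
            np.put_along_axis(
                target_dist, targets[..., None], 1.0 - eps, axis=-1
            )
            grad = (p - target_dist) * mask[..., None] / n
            _accumulate(logits, (g * grad).astype(logits.data.dtype), own=True)

    return Tensor(
        np.asarray(loss, dtype=logits.data.dtype),
        logits.requires_grad,
        (logits,),
        backward if logits.requires_grad else None,
    )
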