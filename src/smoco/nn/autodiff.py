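"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the 3D contrastive pipeline
needs: broadcasting arithmetic, matmul, exp/log, ReLU, reductions,
reshape/transpose, im2col 3D convolution and 2x2x2 max pooling. Graphs
are built eagerly; :func:`backward` runs a topological sweep. A
``no_grad`` context skips graph construction entirely, which is how
momentum (key) encoder forwards and evaluation passes are run.

Gradient correctness for every primitive is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior nodes: free graph-local grad references lazily
        # graph is discarded with the tensors themselves

    # -- operators ------------------------------------------------------------
    def _wrap_like(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def __add__(self, other):
        return add(self, self._wrap_like(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, mul_scalar(self._wrap_like(other), -1.0))

    def __rsub__(self, other):
        return add(self._wrap_like(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, Tensor._wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return mul(self, power(Tensor._wrap(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, Tensor._wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = np.asarray(g, dtype=t.data.dtype)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or g is t.data else g
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- primitives ----------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    data = a.data * s

    def backward(g):
        _accum(a, g * s)

    return _node(data, (a,), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return _node(data, (a, b), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _node(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _node(data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _node(data, (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _node(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accum(a, g.transpose(inv))

    return _node(data, (a,), backward)


def logsumexp(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as constant."""
    m = a.data.max(axis=axis, keepdims=True)
    shifted = add(a, Tensor(-m))
    out = log(tsum(exp(shifted), axis=axis, keepdims=True))
    out = add(out, Tensor(m))
    if not keepdims:
        out = reshape(out, np.squeeze(out.data, axis=axis).shape)
    return out


def l2_normalize(a: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Rows scaled to unit Euclidean norm (the projection-head output map)."""
    sq = tsum(mul(a, a), axis=axis, keepdims=True)
    inv = power(add(sq, Tensor(np.array(eps, dtype=a.data.dtype))), -0.5)
    return mul(a, inv)


# -- spatial primitives --------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation via im2col.

    ``x``: (B, Cin, D, H, W); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,).
    """
    B, Cin, D, H, W = x.data.shape
    Cout, Cin_w, k, _, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Do = (D + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]                        # (B,Cin,Do,Do,Do,k,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    cols = cols.reshape(B, Do * Do * Do, Cin * k ** 3)
    w2d = w.data.reshape(Cout, Cin * k ** 3)
    out = cols @ w2d.T
    if b is not None:
        out = out + b.data
    out = out.reshape(B, Do, Do, Do, Cout).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)

    def backward(g):
        g2d = g.transpose(0, 2, 3, 4, 1).reshape(B, Do * Do * Do, Cout)
        if w.requires_grad:
            gw = np.tensordot(g2d, cols, axes=([0, 1], [0, 1]))
            _accum(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, g2d.sum(axis=(0, 1)))
        if x.requires_grad:
            gcols = g2d @ w2d                              # (B, P, Cin*k^3)
            gcols = gcols.reshape(B, Do, Do, Do, Cin, k, k, k)
            gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            gxp = np.zeros_like(xp)
            for a_ in range(k):
                for b_ in range(k):
                    for c_ in range(k):
                        gxp[:, :,
                            a_: a_ + s * (Do - 1) + 1: s,
                            b_: b_ + s * (Do - 1) + 1: s,
                            c_: c_ + s * (Do - 1) + 1: s] += gcols[..., a_, b_, c_]
            gx = gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp
            _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool3d_2(x: Tensor) -> Tensor:
    """Non-overlapping 2x2x2 max pooling (odd trailing voxels dropped)."""
    B, C, D, H, W = x.data.shape
    Do, Ho, Wo = D // 2, H // 2, W // 2
    xt = x.data[:, :, :2 * Do, :2 * Ho, :2 * Wo]
    xr = xt.reshape(B, C, Do, 2, Ho, 2, Wo, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, Do, Ho, Wo, 8)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((B, C, Do, Ho, Wo, 8), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, Do, Ho, Wo, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        gx = np.zeros_like(x.data)
        gx[:, :, :2 * Do, :2 * Ho, :2 * Wo] = gr.reshape(B, C, 2 * Do, 2 * Ho, 2 * Wo)
        _accum(x, gx)

    return _node(out, (x,), backward)


def norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                mu: Optional[np.ndarray] = None,
                var: Optional[np.ndarray] = None) -> Tensor:
    """Fused per-channel normalize-and-affine for (B, C, D, H, W) input.

    With ``mu``/``var`` omitted they are the batch statistics over axes
    (0, 2, 3, 4) and the backward pass accounts for their dependence on
    ``x``; when given (running statistics) they are treated as
    constants.
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    batch_stats = mu is None
    if batch_stats:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    else:
        mu = np.asarray(mu, dtype=x.data.dtype).reshape(shape)
        var = np.asarray(var, dtype=x.data.dtype).reshape(shape)
    inv_std = 1.0 / np.sqrt(var + eps)
    xn = (x.data - mu) * inv_std
    out = xn * gamma.data.reshape(shape) + beta.data.reshape(shape)

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xn).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(shape)
            if batch_stats:
                n = x.data.size // x.data.shape[1]
                gm = gs.sum(axis=axes, keepdims=True) / n
                gxn = (gs * xn).sum(axis=axes, keepdims=True) / n
                _accum(x, inv_std * (gs - gm - xn * gxn))
            else:
                _accum(x, gs * inv_std)

    return _node(out, (x, gamma, beta), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``targets`` are integer class indices."""
    n = logits.data.shape[0]
    lse = logsumexp(logits, axis=1, keepdims=True)
    logp = add(logits, mul_scalar(lse, -1.0))
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(n), targets] = 1.0
    picked = mul(logp, Tensor(onehot))
    return mul_scalar(tsum(picked), -1.0 / n)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    lse = logsumexp(a, axis=axis, keepdims=True)
    return exp(add(a, mul_scalar(lse, -1.0)))


def concat_rows(tensors: Iterable[Tensor]) -> Tensor:
    """Concatenate 2D tensors along axis 0."""
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=0)
    sizes = [t.data.shape[0] for t in ts]

    def backward(g):
        off = 0
        for t, sz in zip(ts, sizes):
            _accum(t, g[off:off + sz])
            off += sz

    return _node(data, tuple(ts), backward)
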