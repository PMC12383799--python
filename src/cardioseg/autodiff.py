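"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the segmentation networks and losses
need: broadcast arithmetic, reductions, leaky ReLU, dropout, same-padded
stride-1 N-D convolution (via im2col + BLAS matmul), factor-2 average
pooling, factor-2 linear upsampling, channel concatenation and channel
softmax.  Gradients are accumulated on leaf tensors by :meth:`Tensor.backward`
using an iterative topological sort.

Tensors wrap ``numpy`` arrays without copying.  An op only records a backward
closure when at least one input requires gradients, so inference-mode
forward passes carry no tape overhead.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "leaky_relu",
    "dropout",
    "conv_nd",
    "avg_pool",
    "upsample_linear",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        """A view of this tensor cut out of the graph (stop-gradient)."""
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order over the subgraph that requires grad
        topo, seen, stack = [], set(), [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda a, b, g: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide,
            lambda a, b, g: (g / b.data, -g * a.data / (b.data * b.data)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1))
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, shape))
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for a in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, a)
                self._accumulate(np.broadcast_to(gg, shape))

            out._parents = (self,)
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _binary(a, b, fwd, bw_pair) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), a.requires_grad or b.requires_grad)
    if out.requires_grad:
        def bw(g):
            ga, gb = bw_pair(a, b, g)
            if a.requires_grad:
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(gb, b.data.shape))
        out._parents = (a, b)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# neural-network ops
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    x = as_tensor(x)
    neg = x.data < 0
    out_data = np.where(neg, x.data * slope, x.data)
    out = Tensor(out_data, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(np.where(neg, g * slope, g))
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted element-wise dropout; identity when ``rate`` is 0."""
    x = as_tensor(x)
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    out = Tensor(x.data * mask, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """``x`` (C, *S) -> columns (prod(S), C * k**d), same zero padding."""
    d = x.ndim - 1
    pad = k // 2
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * d)
    win = sliding_window_view(xp, (k,) * d, axis=tuple(range(1, d + 1)))
    # win: (C, *S, *k) -> (*S, C, *k)
    order = tuple(range(1, d + 1)) + (0,) + tuple(range(d + 1, 2 * d + 1))
    n_spatial = int(np.prod(x.shape[1:]))
    return np.ascontiguousarray(win.transpose(order)).reshape(
        n_spatial, x.shape[0] * k ** d)


def _conv_raw(x: np.ndarray, w: np.ndarray, b=None):
    """Forward N-D convolution; returns (out, cols) with cols for reuse."""
    f = w.shape[0]
    cols = _im2col(x, w.shape[2])
    out = cols @ w.reshape(f, -1).T            # (prod(S), F)
    out = np.ascontiguousarray(out.T).reshape((f,) + x.shape[1:])
    if b is not None:
        out += b.reshape((f,) + (1,) * (x.ndim - 1))
    return out, cols


def conv_nd(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution.

    ``x``: (C_in, *S); ``w``: (C_out, C_in, *k) with odd cubic kernel;
    ``b``: (C_out,).  Output (C_out, *S).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    needs = x.requires_grad or w.requires_grad or b.requires_grad
    out_data, cols = _conv_raw(x.data, w.data, b.data)
    out = Tensor(out_data, needs)
    if needs:
        k = w.data.shape[2]
        d = x.data.ndim - 1
        spatial_axes = tuple(range(1, d + 1))

        def bw(g):
            f = w.data.shape[0]
            g_mat = g.reshape(f, -1)
            if b.requires_grad:
                b._accumulate(g.sum(axis=spatial_axes))
            if w.requires_grad:
                w._accumulate((g_mat @ cols).reshape(w.data.shape))
            if x.requires_grad:
                # input gradient = same-padded conv of g with the
                # channel-swapped, spatially flipped kernel
                w_t = np.flip(w.data, axis=tuple(range(2, 2 + d)))
                w_t = np.ascontiguousarray(np.swapaxes(w_t, 0, 1))
                gx, _ = _conv_raw(g, w_t)
                x._accumulate(gx)

        out._parents = (x, w, b)
        out._backward = bw
    return out


def avg_pool(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling over all spatial axes of (C, *S)."""
    x = as_tensor(x)
    d = x.data.ndim - 1
    if any(s % factor for s in x.data.shape[1:]):
        raise ValueError(f"spatial extent {x.data.shape[1:]} not divisible by {factor}")
    new_shape = [x.data.shape[0]]
    for s in x.data.shape[1:]:
        new_shape += [s // factor, factor]
    reduce_axes = tuple(range(2, 2 * d + 1, 2))
    out = Tensor(x.data.reshape(new_shape).mean(axis=reduce_axes),
                 x.requires_grad)
    if out.requires_grad:
        def bw(g):
            gg = g / factor ** d
            for axis in range(1, d + 1):
                gg = np.repeat(gg, factor, axis=axis)
            x._accumulate(gg)
        out._parents = (x,)
        out._backward = bw
    return out


def _up_indices(n: int):
    """Index/weight scheme for 1-D linear x2 upsampling (edge clamped)."""
    j = np.arange(2 * n)
    base = j // 2
    other = np.where(j % 2 == 0, np.maximum(base - 1, 0),
                     np.minimum(base + 1, n - 1))
    return base, other


def upsample_linear(x: Tensor, factor: int = 2) -> Tensor:
    """Linear (bi-/tri-linear) upsampling by 2 over all spatial axes.

    Output sample ``2i`` mixes inputs ``i`` and ``i-1`` with weights
    0.75/0.25, sample ``2i+1`` mixes ``i`` and ``i+1``; edges clamp.
    """
    if factor != 2:
        raise NotImplementedError("only factor-2 upsampling is supported")
    x = as_tensor(x)
    d = x.data.ndim - 1
    data = x.data
    idx_pairs = []
    for axis in range(1, d + 1):
        base, other = _up_indices(data.shape[axis])
        idx_pairs.append((axis, base, other))
        data = 0.75 * np.take(data, base, axis=axis) \
            + 0.25 * np.take(data, other, axis=axis)
    out = Tensor(data, x.requires_grad)
    if out.requires_grad:
        def bw(g):
            for axis, base, other in reversed(idx_pairs):
                gm = np.moveaxis(g, axis, 0)
                n = (gm.shape[0]) // 2
                acc = np.zeros((n,) + gm.shape[1:], dtype=gm.dtype)
                np.add.at(acc, base, 0.75 * gm)
                np.add.at(acc, other, 0.25 * gm)
                g = np.moveaxis(acc, 0, axis)
            x._accumulate(g)
        out._parents = (x,)
        out._backward = bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, x.requires_grad)
    if out.requires_grad:
        def bw(g):
            x._accumulate(p * (g - (p * g).sum(axis=axis, keepdims=True)))
        out._parents = (x,)
        out._backward = bw
    return out
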