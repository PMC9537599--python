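"""Minimal reverse-mode automatic differentiation on numpy arrays.

The backward rule of every primitive is itself expressed in terms of
primitives, so gradients are ordinary graph nodes and can be differentiated
again.  This second-order capability is what the Wasserstein critic's
gradient penalty requires: the penalty is a function of ``d(critic)/d(input)``
and its parameter gradient needs backprop *through* a backprop.

Each node stores one vector-Jacobian product callable per parent
(``_vjps``); the backward driver only invokes the callables of parents that
actually require gradients, so multiply-by-constant branches cost nothing.

Only the operations used by the networks in this package are provided.
Shapes follow numpy broadcasting; images are NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "grad", "concat", "matmul", "unfold",
           "fold", "upsample_nearest2", "sumpool2", "group_norm"]


class Tensor:
    """A numpy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._vjps = vjps

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    # -- composite helpers ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else int(np.prod(
            [self.shape[a] for a in _norm_axes(axis, self.ndim)]))
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, i, j):
        return swapaxes(self, i, j)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, np.ndarray):
        return Tensor(x)
    # scalar constants become float32 so they never upcast float32 graphs;
    # float64 graphs still win the usual numpy promotion
    return Tensor(np.asarray(x, dtype=np.float32))


def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` (differentiable)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, parents=(a, b),
                  vjps=(lambda g: _unbroadcast(g, a.shape),
                        lambda g: _unbroadcast(g, b.shape)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), vjps=(lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data, parents=(a, b),
                  vjps=(lambda g: _unbroadcast(mul(g, b), a.shape),
                        lambda g: _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data / b.data, parents=(a, b),
                  vjps=(lambda g: _unbroadcast(div(g, b), a.shape),
                        lambda g: _unbroadcast(
                            neg(mul(g, div(a, mul(b, b)))), b.shape)))


def pow_const(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return Tensor(a.data ** p, parents=(a,),
                  vjps=(lambda g: mul(g, mul(
                      Tensor(np.asarray(p, dtype=np.float32)),
                      pow_const(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,))
    out._vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), parents=(a,),
                  vjps=(lambda g: div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), parents=(a,))
    out._vjps = (lambda g: div(g, mul(as_tensor(2.0), out)),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), parents=(a,))
    out._vjps = (lambda g: mul(g, as_tensor(1.0) - mul(out, out)),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-a.data)), parents=(a,))
    out._vjps = (lambda g: mul(g, mul(out, as_tensor(1.0) - out)),)
    return out


def silu(a: Tensor) -> Tensor:
    return mul(a, sigmoid(a))


def absval(a: Tensor) -> Tensor:
    return Tensor(np.abs(a.data), parents=(a,),
                  vjps=(lambda g: mul(g, Tensor(np.sign(a.data))),))


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient passes through only inside [lo, hi]."""
    mask = Tensor(((a.data >= lo) & (a.data <= hi)).astype(a.dtype))
    return Tensor(np.clip(a.data, lo, hi), parents=(a,),
                  vjps=(lambda g: mul(g, mask),))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    axes = _norm_axes(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)
    kd_shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))

    def vjp(g):
        gk = g if keepdims or not kd_shape else reshape(g, kd_shape)
        return broadcast_to(gk, a.shape)

    return Tensor(out_data, parents=(a,), vjps=(vjp,))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(np.broadcast_to(a.data, shape), parents=(a,),
                  vjps=(lambda g: _unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(a.data.reshape(shape), parents=(a,),
                  vjps=(lambda g: reshape(g, a.shape),))


def swapaxes(a: Tensor, i: int, j: int) -> Tensor:
    return Tensor(np.swapaxes(a.data, i, j), parents=(a,),
                  vjps=(lambda g: swapaxes(g, i, j),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(np.matmul(a.data, b.data), parents=(a, b),
                  vjps=(lambda g: _unbroadcast(
                            matmul(g, swapaxes(b, -1, -2)), a.shape),
                        lambda g: _unbroadcast(
                            matmul(swapaxes(a, -1, -2), g), b.shape)))


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    starts = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(i):
        return lambda g: narrow(g, axis, int(starts[i]),
                                int(starts[i + 1] - starts[i]))

    return Tensor(out_data, parents=tuple(tensors),
                  vjps=tuple(make_vjp(i) for i in range(len(tensors))))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    return Tensor(a.data[tuple(idx)], parents=(a,),
                  vjps=(lambda g: pad_slice(g, a.shape, axis, start),))


def pad_slice(a: Tensor, full_shape, axis: int, start: int) -> Tensor:
    """Embed ``a`` into a zero array of ``full_shape`` along ``axis``."""
    full_shape = tuple(full_shape)
    length = a.shape[axis]
    out_data = np.zeros(full_shape, dtype=a.dtype)
    idx = [slice(None)] * len(full_shape)
    idx[axis] = slice(start, start + length)
    out_data[tuple(idx)] = a.data
    return Tensor(out_data, parents=(a,),
                  vjps=(lambda g: narrow(g, axis, start, length),))


# -- image primitives (linear adjoint pairs) --------------------------------

def unfold(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    """im2col: (N,C,H,W) -> (N, C*k*k, L) of sliding k x k patches."""
    N, C, H, W = x.shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]             # (N,C,Ho,Wo,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    cols = cols.reshape(N, C * k * k, Ho * Wo)
    return Tensor(cols, parents=(x,),
                  vjps=(lambda g: fold(g, (N, C, H, W), k, stride, padding),))


def fold(cols: Tensor, x_shape, k: int, stride: int = 1,
         padding: int = 0) -> Tensor:
    """col2im: adjoint of :func:`unfold` (overlaps are summed)."""
    N, C, H, W = x_shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    colsr = cols.data.reshape(N, C, k, k, Ho, Wo)
    Hp, Wp = H + 2 * padding, W + 2 * padding
    out = np.zeros((N, C, Hp, Wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * Ho:stride,
                j:j + stride * Wo:stride] += colsr[:, :, i, j]
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return Tensor(out, parents=(cols,),
                  vjps=(lambda g: unfold(g, k, stride, padding),))


def upsample_nearest2(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    return Tensor(out_data, parents=(x,), vjps=(lambda g: sumpool2(g),))


def sumpool2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    out_data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
    return Tensor(out_data, parents=(x,),
                  vjps=(lambda g: upsample_nearest2(g),))


def softmax_lastdim(a: Tensor) -> Tensor:
    shift = Tensor(a.data.max(axis=-1, keepdims=True))   # constant for grads
    e = exp(a - shift)
    return div(e, tsum(e, axis=-1, keepdims=True))


def group_norm(x: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Fused group normalization of an NCHW map (no affine part).

    The forward pass runs in plain numpy; the backward rule uses the
    closed-form group-norm gradient expressed in primitives, so it stays
    differentiable (needed when a critic containing normalization layers
    sits under a gradient penalty).
    """
    N, C, H, W = x.shape
    m = (C // groups) * H * W
    xg = x.data.reshape(N, groups, m)
    mu = xg.mean(axis=2, keepdims=True)
    xc = xg - mu
    var = (xc * xc).mean(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out = Tensor((xc * inv).reshape(N, C, H, W), parents=(x,))

    def vjp(g):
        # statistics rebuilt from the graph so the rule is differentiable
        xg_t = reshape(x, (N, groups, m))
        mu_t = tsum(xg_t, axis=2, keepdims=True) * (1.0 / m)
        xc_t = xg_t - mu_t
        var_t = tsum(mul(xc_t, xc_t), axis=2, keepdims=True) * (1.0 / m)
        inv_t = pow_const(var_t + eps, -0.5)
        xn_t = mul(xc_t, inv_t)
        gg = reshape(g, (N, groups, m))
        mean_g = tsum(gg, axis=2, keepdims=True) * (1.0 / m)
        mean_gx = tsum(mul(gg, xn_t), axis=2, keepdims=True) * (1.0 / m)
        gx = mul(inv_t, gg - mean_g - mul(xn_t, mean_gx))
        return reshape(gx, (N, C, H, W))

    out._vjps = (vjp,)
    return out


# ---------------------------------------------------------------------------
# backward driver
# ---------------------------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None, create_graph=False,
         accumulate=False):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients stay connected to the
    graph and can be differentiated again.  With ``accumulate=True`` the
    gradients are also added into each input's ``.grad`` slot (numpy array).
    """
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    keep = {id(t) for t in inputs}
    grads = {id(output): grad_output}
    result = {id(output): grad_output} if id(output) in keep else {}
    for node in reversed(_topo(output)):
        g = grads.pop(id(node), None)
        if g is None or node._vjps is None:
            continue
        for p, vjp in zip(node._parents, node._vjps):
            if not p.requires_grad:
                continue
            pg = vjp(g)
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
            if id(p) in keep:
                result[id(p)] = grads[id(p)]
    out = []
    for t in inputs:
        g = result.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        if not create_graph:
            g = g.detach()
        if accumulate:
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            t.grad = t.grad + g.data
        out.append(g)
    return out
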