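"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`fallgcn.network` needs gradients for a handful of array
operations (1x1 channel maps, temporal convolutions, graph aggregation,
pooling, batch normalisation, masked softmax, dense layers).  This module
provides exactly those as a small tape-based autodiff engine: every operation
returns a :class:`Tensor` that remembers its parents and a closure computing
the local vector-Jacobian product.  ``backward`` walks the tape in reverse
topological order.

All gradients are checked against central finite differences in the test
suite; the engine is deliberately small rather than general.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "scale", "relu", "sigmoid", "concat",
    "transpose", "reshape", "index_axis", "mean_axis", "max_axis",
    "conv1x1", "dense",
    "temporal_conv", "node_map", "masked_softmax", "batch_norm",
    "cross_entropy", "SGD",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort: graphs can be deep
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    def _accum(self, g, owned=False):
        # ``owned`` promises g is a freshly allocated buffer no other node
        # aliases, so it can be adopted without a defensive copy
        if self.grad is None:
            self.grad = g if owned else np.array(g)
        else:
            self.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, vjp):
    out = Tensor(data, parents=parents)
    if out.requires_grad:
        out._vjp = vjp
    return out


# ---------------------------------------------------------------- elementwise

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    def vjp(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))
    return _make(a.data + b.data, (a, b), vjp)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    def vjp(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.shape))
    return _make(a.data - b.data, (a, b), vjp)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    def vjp(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape), owned=True)
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape), owned=True)
    return _make(a.data * b.data, (a, b), vjp)


def scale(a, c):
    a = _as_tensor(a)
    c = float(c)
    def vjp(g):
        if a.requires_grad:
            a._accum(g * c, owned=True)
    return _make(a.data * c, (a,), vjp)


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    def vjp(g):
        if x.requires_grad:
            x._accum(g * mask, owned=True)
    return _make(x.data * mask, (x,), vjp)


def sigmoid(x):
    x = _as_tensor(x)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-x.data))
    def vjp(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s), owned=True)
    return _make(s, (x,), vjp)


# ------------------------------------------------------------------ structure

def concat(tensors, axis):
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def vjp(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), vjp)


def transpose(x, axes):
    x = _as_tensor(x)
    inv = np.argsort(axes)
    def vjp(g):
        if x.requires_grad:
            x._accum(np.transpose(g, inv))
    return _make(np.transpose(x.data, axes), (x,), vjp)


def reshape(x, shape):
    x = _as_tensor(x)
    old = x.shape
    def vjp(g):
        if x.requires_grad:
            x._accum(g.reshape(old))
    return _make(x.data.reshape(shape), (x,), vjp)


def index_axis(x, axis, i):
    """Select index ``i`` along ``axis`` (the axis is dropped)."""
    x = _as_tensor(x)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = i
    sl = tuple(sl)
    def vjp(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x._accum(gx, owned=True)
    return _make(x.data[sl], (x,), vjp)


def mean_axis(x, axis, keepdims=False):
    x = _as_tensor(x)
    axis = (axis,) if isinstance(axis, int) else tuple(axis)
    n = int(np.prod([x.shape[a] for a in axis]))
    def vjp(g):
        if x.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            x._accum(np.broadcast_to(gg, x.shape) / n, owned=True)
    return _make(x.data.mean(axis=axis, keepdims=keepdims), (x,), vjp)


def max_axis(x, axis, keepdims=False):
    """Maximum along one axis; ties route gradient to the first maximum."""
    x = _as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis)
    def vjp(g):
        if x.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), gg, axis=axis)
            x._accum(gx, owned=True)
    return _make(out if keepdims else np.squeeze(out, axis=axis), (x,), vjp)


# --------------------------------------------------------------------- layers

def _channel_map(x, wt):
    # (N,C,T,V) mapped by wt (D,C) -> (N,D,T,V) via one GEMM per sample
    n, c, t, v = x.shape
    return np.matmul(wt, x.reshape(n, c, t * v)).reshape(
        n, wt.shape[0], t, v)


def conv1x1(x, w, b=None):
    """Per-position channel map: x (N,C,T,V), w (C,D), b (D,) -> (N,D,T,V)."""
    x, w = _as_tensor(x), _as_tensor(w)
    out = _channel_map(x.data, w.data.T)
    if b is not None:
        b = _as_tensor(b)
        out += b.data[None, :, None, None]
    def vjp(g):
        if x.requires_grad:
            x._accum(_channel_map(g, w.data), owned=True)
        if w.requires_grad:
            w._accum(np.tensordot(x.data, g, axes=([0, 2, 3], [0, 2, 3])),
                     owned=True)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)), owned=True)
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, vjp)


def dense(x, w, b=None):
    """Affine map on the last axis: x (..., F), w (F, G), b (G,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    out = x.data @ w.data
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data
    def vjp(g):
        if x.requires_grad:
            x._accum(g @ w.data.T, owned=True)
        if w.requires_grad:
            f, gg = w.shape
            w._accum(x.data.reshape(-1, f).T @ g.reshape(-1, gg), owned=True)
        if b is not None and b.requires_grad:
            b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0), owned=True)
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, vjp)


def temporal_conv(x, w, b=None):
    """Convolution along the frame axis with same-length zero padding.

    x: (N, C, T, V); w: (K, C, D) with K odd; output (N, D, T, V).
    out[n,d,t,v] = sum_k sum_c w[k,c,d] * xpad[n,c,t+k,v]
    """
    x, w = _as_tensor(x), _as_tensor(w)
    K = w.shape[0]
    if K % 2 == 0:
        raise ValueError("temporal kernel size must be odd")
    pad = K // 2
    T = x.shape[2]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (0, 0)))
    out = np.zeros((x.shape[0], w.shape[2], T, x.shape[3]),
                   dtype=np.result_type(x.data, w.data))
    for k in range(K):
        out += _channel_map(np.ascontiguousarray(xp[:, :, k:k + T, :]),
                            w.data[k].T)
    if b is not None:
        b = _as_tensor(b)
        out += b.data[None, :, None, None]
    def vjp(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + T, :] += _channel_map(g, w.data[k])
            x._accum(np.ascontiguousarray(gxp[:, :, pad:pad + T, :]),
                     owned=True)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(K):
                gw[k] = np.tensordot(
                    np.ascontiguousarray(xp[:, :, k:k + T, :]), g,
                    axes=([0, 2, 3], [0, 2, 3]))
            w._accum(gw, owned=True)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)), owned=True)
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, vjp)


def node_map(x, m):
    """Linear map over the joint axis with a matrix ``m``: (U,V).

    out[..., u] = sum_v m[u, v] * x[..., v].  Used both for neighbour
    aggregation (m = adjacency subset, possibly trainable) and for constant
    gather/scatter matrices when slicing body parts in and out.
    """
    x, m = _as_tensor(x), _as_tensor(m)
    out = x.data @ m.data.T
    def vjp(g):
        if x.requires_grad:
            x._accum(g @ m.data, owned=True)
        if m.requires_grad:
            U, V = m.shape
            m._accum(g.reshape(-1, U).T @ x.data.reshape(-1, V), owned=True)
    return _make(out, (x, m), vjp)


def masked_softmax(x, mask, axis):
    """Softmax along ``axis`` restricted to positions where mask is True.

    Masked-out positions get probability exactly 0.  Rows with no valid
    position stay all-zero.
    """
    x = _as_tensor(x)
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, x.data, -np.inf)
    mx = np.max(neg, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.exp(np.where(mask, x.data - mx, -np.inf))
    e = np.where(mask, e, 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    def vjp(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            x._accum(p * (g - dot), owned=True)
    return _make(p, (x,), vjp)


def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5, feature_axis=-1):
    """Batch normalisation per feature along ``feature_axis`` (statistics
    over every other axis).

    ``running_mean``/``running_var`` are plain numpy buffers updated in place
    during training and used verbatim at evaluation time.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    nd = x.data.ndim
    fa = feature_axis % nd
    axes = tuple(a for a in range(nd) if a != fa)
    bshape = [1] * nd
    bshape[fa] = x.shape[fa]
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).reshape(bshape)
    xhat = (x.data - mean.reshape(bshape)) * inv
    out = xhat * gamma.data.reshape(bshape) + beta.data.reshape(bshape)
    n = int(np.prod([x.shape[a] for a in axes]))
    def vjp(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes), owned=True)
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes), owned=True)
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(bshape)
            if training:
                gx = inv * (
                    gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=axes,
                                                keepdims=True) / n)
            else:
                gx = gxhat * inv
            x._accum(gx, owned=True)
    return _make(out, (x, gamma, beta), vjp)


def cross_entropy(logits, labels):
    """Mean cross-entropy of integer ``labels`` under softmax(logits)."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsum
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    def vjp(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(g * p / n, owned=True)
    return _make(loss, (logits,), vjp)


def softmax_probs(logits):
    """Plain softmax as numpy (inference only, no gradient)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ------------------------------------------------------------------ optimiser

class SGD:
    """Stochastic gradient descent with Nesterov momentum and weight decay.

    Follows the common deep-learning convention: the L2 penalty is folded
    into the gradient (d <- g + wd*p), the velocity is v <- m*v + d, and the
    Nesterov step uses d + m*v.
    """

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0,
                 nesterov=True):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.nesterov = bool(nesterov)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if not p.requires_grad:
                continue
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            d = g + self.weight_decay * p.data
            v *= self.momentum
            v += d
            if self.nesterov and self.momentum > 0:
                d = d + self.momentum * v
            else:
                d = v
            p.data -= self.lr * d
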