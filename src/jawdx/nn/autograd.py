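"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are deliberately small (desk-scale profiles of a
two-branch convolutional model), so a compact tape-based autodiff engine on
float32 arrays is sufficient and keeps every run bit-reproducible on one CPU.

A :class:`Tensor` wraps an ``ndarray`` and remembers, for each op, how to push
an output gradient back to its inputs.  :func:`backward` walks the tape in
reverse topological order and returns a :class:`Grads` lookup keyed by tensor
identity, so the same graph can be differentiated several times with
independent gradient stores (used for Grad-CAM, where the class-score gradient
is computed separately from the training-loss gradient).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # the networks are tiny; float32 halves the memory
                    # traffic that dominates conv cost on one CPU

__all__ = [
    "Tensor", "astensor", "backward", "Grads",
    "add", "sub", "mul", "neg", "scale", "matmul", "relu", "sigmoid",
    "log_softmax", "ssum", "smean", "reshape", "concat", "conv2d",
    "batchnorm_train", "batchnorm_eval",
    "global_avg_pool", "upsample2", "take_rows", "l2_normalize", "square",
]


class Tensor:
    """An ndarray plus the backward closures linking it to its inputs."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.parents = parents

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, leaf={not self.parents})"

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __truediv__(self, c):
        if isinstance(c, Tensor):
            raise TypeError("tensor/tensor division not supported")
        return scale(self, 1.0 / float(c))

    def __matmul__(self, other):
        return matmul(self, other)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        ((a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(g, b.data.shape))),
    )


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data - b.data,
        ((a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(-g, b.data.shape))),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        ((a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(g * a.data, b.data.shape))),
    )


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.data, ((a, lambda g: -g),))


def scale(a, c: float) -> Tensor:
    a = astensor(a)
    c = float(c)
    return Tensor(a.data * c, ((a, lambda g: g * c),))


def square(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.data * a.data, ((a, lambda g: 2.0 * a.data * g),))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return Tensor(
        a.data @ b.data,
        ((a, lambda g: g @ b.data.T),
         (b, lambda g: a.data.T @ g)),
    )


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, ((a, lambda g: g * mask),))


def sigmoid(a) -> Tensor:
    a = astensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(s, ((a, lambda g: g * s * (1.0 - s)),))


def log_softmax(a, axis: int = 1) -> Tensor:
    a = astensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    soft = np.exp(out)

    def back(g):
        return g - soft * g.sum(axis=axis, keepdims=True)

    return Tensor(out, ((a, back),))


def ssum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return Tensor(out, ((a, back),))


def smean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return scale(ssum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(a.data.reshape(shape), ((a, lambda g: g.reshape(a.data.shape)),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_back(i):
        sl = [slice(None)] * tensors[i].data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    parents = tuple((t, make_back(i)) for i, t in enumerate(tensors))
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents)


def conv2d(x, w, b=None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) in NCHW layout via im2col."""
    x, w = astensor(x), astensor(w)
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    f, cin, kh, kw = wd.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (wid + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, oh, ow, kh, kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    out = cols @ wd.reshape(f, -1).T  # n, oh*ow, f
    outd = np.ascontiguousarray(out.transpose(0, 2, 1).reshape(n, f, oh, ow))
    if b is not None:
        b = astensor(b)
        outd = outd + b.data.reshape(1, f, 1, 1)

    def gx(g):
        gcols = g.reshape(n, f, oh * ow).transpose(0, 2, 1) @ wd.reshape(f, -1)
        # one contiguous relayout so the scatter loop adds views, not copies
        gcols = np.ascontiguousarray(
            gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2))
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + oh * stride:stride,
                    j:j + ow * stride:stride] += gcols[:, :, i, j]
        if pad:
            return gxp[:, :, pad:pad + h, pad:pad + wid]
        return gxp

    def gw(g):
        gflat = g.reshape(n, f, oh * ow).transpose(1, 0, 2).reshape(f, -1)
        return (gflat @ cols.reshape(n * oh * ow, -1)).reshape(wd.shape)

    parents = [(x, gx), (w, gw)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(outd, tuple(parents))


def batchnorm_train(x, gamma, beta, eps: float = 1e-5):
    """Batch normalisation over (N, H, W) per channel, training mode.

    Returns ``(out, batch_mean, batch_var)``; the caller maintains the
    statistics used at inference.  Gradients flow through the batch
    statistics (the standard training-mode backward).
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    xd = x.data
    n, c, h, w = xd.shape
    m = n * h * w
    mean = xd.mean(axis=(0, 2, 3))
    var = xd.var(axis=(0, 2, 3))
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + \
        beta.data[None, :, None, None]

    def gx(g):
        dxhat = g * gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        return (ivstd[None, :, None, None] / m) * (
            m * dxhat - s1[None, :, None, None]
            - xhat * s2[None, :, None, None])

    parents = (
        (x, gx),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    )
    return Tensor(out, parents), mean, var


def batchnorm_eval(x, gamma, beta, running_mean, running_var,
                   eps: float = 1e-5) -> Tensor:
    """Batch normalisation with frozen statistics (inference mode)."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    ivstd = 1.0 / np.sqrt(running_var + eps)
    scale_c = (gamma.data * ivstd)[None, :, None, None]
    shift = (beta.data - gamma.data * running_mean * ivstd)[None, :, None,
                                                            None]
    out = x.data * scale_c + shift
    xhat = (x.data - running_mean[None, :, None, None]) * \
        ivstd[None, :, None, None]
    parents = (
        (x, lambda g: g * scale_c),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    )
    return Tensor(out, parents)


def global_avg_pool(x) -> Tensor:
    x = astensor(x)
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def back(g):
        return np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy()

    return Tensor(out, ((x, back),))


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def back(g):
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    return Tensor(out, ((x, back),))


def take_rows(x, idx) -> Tensor:
    x = astensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def back(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(x.data[idx], ((x, back),))


def l2_normalize(x, axis: int = 1, eps: float = 1e-8) -> Tensor:
    x = astensor(x)
    norm = np.sqrt((x.data ** 2).sum(axis=axis, keepdims=True))
    if np.any(norm < eps):
        raise ValueError("cannot L2-normalise a zero-norm vector")
    y = x.data / norm

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (g - y * dot) / norm

    return Tensor(y, ((x, back),))


class Grads:
    """Gradient lookup keyed by tensor identity."""

    def __init__(self, store: dict):
        self._store = store

    def __getitem__(self, t: Tensor) -> np.ndarray:
        return self._store[id(t)]

    def __contains__(self, t: Tensor) -> bool:
        return id(t) in self._store

    def get(self, t: Tensor, default=None):
        return self._store.get(id(t), default)


def backward(root: Tensor, seed=None) -> Grads:
    """Reverse-mode sweep from ``root``; returns gradients w.r.t. every node.

    ``seed`` is the output gradient (defaults to ones, so a scalar root yields
    plain derivatives).
    """
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in visited:
                stack.append((parent, False))
    if seed is None:
        seed_arr = np.ones_like(root.data)
    else:
        seed_arr = np.broadcast_to(np.asarray(seed, dtype=DTYPE),
                                   root.data.shape).copy()
    grads: dict[int, np.ndarray] = {id(root): seed_arr}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, fn in node.parents:
            pg = fn(g)
            if id(parent) in grads:
                grads[id(parent)] = grads[id(parent)] + pg
            else:
                grads[id(parent)] = pg
    return Grads(grads)
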