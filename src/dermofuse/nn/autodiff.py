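"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute core of the package: a small define-by-run tape
restricted to the operations the fusion networks need (2-D convolution,
dense layers, elementwise gates, reductions, concatenation, zero padding
and a softmax cross-entropy loss).  Tensors follow the NHWC layout
(batch, height, width, channels) throughout.

The engine favours clarity over generality: convolutions are computed as
a sum of strided matrix products over kernel offsets, which keeps peak
memory proportional to one feature map instead of a full im2col buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "Param",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "pad2d",
    "concat",
    "mean_reduce",
    "max_reduce",
    "maximum",
    "reshape",
    "scale",
    "softmax",
    "softmax_cross_entropy",
    "backward",
]


class Var:
    """A node in the autodiff graph holding a float array and its gradient."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "name")

    def __init__(self, data, parents=(), backward_fn=None, name=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.data.shape}, name={self.name!r})"


class Param(Var):
    """A trainable leaf.  ``trainable`` gates optimizer updates (freezing)."""

    __slots__ = ("trainable",)

    def __init__(self, data, name=None, trainable=True):
        super().__init__(data, name=name)
        self.trainable = trainable


def _accum(var, g):
    if var.grad is None:
        var.grad = g.astype(np.float32, copy=True)
    else:
        var.grad += g


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Var, b: Var) -> Var:
    out_data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Var(out_data, (a, b), bw)


def mul(a: Var, b: Var) -> Var:
    out_data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Var(out_data, (a, b), bw)


def scale(a: Var, k: float) -> Var:
    out = Var(a.data * k, (a,))
    out.backward_fn = lambda g: _accum(a, g * k)
    return out


def matmul(x: Var, w: Var) -> Var:
    out_data = x.data @ w.data

    def bw(g):
        _accum(x, g @ w.data.T)
        _accum(w, x.data.T @ g)

    return Var(out_data, (x, w), bw)


def relu(x: Var) -> Var:
    mask = x.data > 0
    out = Var(x.data * mask, (x,))
    out.backward_fn = lambda g: _accum(x, g * mask)
    return out


def sigmoid(x: Var) -> Var:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    s = s.astype(np.float32)
    out = Var(s, (x,))
    out.backward_fn = lambda g: _accum(x, g * s * (1.0 - s))
    return out


def same_pad_amounts(size: int, k: int, s: int) -> tuple[int, int]:
    """'same' padding (TensorFlow convention): output = ceil(size / s),
    total padding split with the extra pixel on the bottom/right."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Var, w: Var, b: Var | None = None, stride: int = 1,
           padding: str = "valid") -> Var:
    """2-D convolution, NHWC input, kernel ``(kh, kw, c_in, c_out)``."""
    n, h, wd, cin = x.data.shape
    kh, kw, wcin, cout = w.data.shape
    if wcin != cin:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {wcin}")
    s = stride
    if padding == "same":
        pt, pb = same_pad_amounts(h, kh, s)
        pl, pr = same_pad_amounts(wd, kw, s)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = x.data
    if pt or pb or pl or pr:
        xp = np.pad(xp, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"conv2d output would be empty for input {x.data.shape}")
    out_data = np.zeros((n, ho, wo, cout), dtype=np.float32)
    wk = w.data
    for ki in range(kh):
        for kj in range(kw):
            patch = xp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
            out_data += (patch.reshape(-1, cin) @ wk[ki, kj]).reshape(n, ho, wo, cout)
    if b is not None:
        out_data += b.data

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(wk)
        for ki in range(kh):
            for kj in range(kw):
                patch = xp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
                gw[ki, kj] = patch.reshape(-1, cin).T @ g.reshape(-1, cout)
                gxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += \
                    (g.reshape(-1, cout) @ wk[ki, kj].T).reshape(n, ho, wo, cin)
        if pt or pb or pl or pr:
            gx = gxp[:, pt:hp - pb, pl:wp - pr, :]
        else:
            gx = gxp
        _accum(x, gx)
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2)))

    return Var(out_data, parents, bw)


def pad2d(x: Var, rings: int) -> Var:
    """Surround each spatial map with ``rings`` rings of zeros."""
    if rings < 0:
        raise ValueError("rings must be non-negative")
    if rings == 0:
        return x
    r = rings
    out_data = np.pad(x.data, ((0, 0), (r, r), (r, r), (0, 0)))
    out = Var(out_data, (x,))
    out.backward_fn = lambda g: _accum(x, g[:, r:-r, r:-r, :])
    return out


def concat(xs: list[Var], axis: int = -1) -> Var:
    datas = [v.data for v in xs]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for v, piece in zip(xs, np.split(g, splits, axis=axis)):
            _accum(v, piece)

    return Var(out_data, tuple(xs), bw)


def mean_reduce(x: Var, axes, keepdims: bool = True) -> Var:
    axes = tuple(axes) if not np.isscalar(axes) else (axes,)
    out_data = x.data.mean(axis=axes, keepdims=keepdims)
    count = np.prod([x.data.shape[a] for a in axes])

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(x, np.broadcast_to(g / count, x.data.shape))

    return Var(out_data, (x,), bw)


def max_reduce(x: Var, axes, keepdims: bool = True) -> Var:
    axes = tuple(axes) if not np.isscalar(axes) else (axes,)
    out_data = x.data.max(axis=axes, keepdims=True)
    mask = (x.data == out_data)
    # split gradient evenly among ties (ties are rare with float activations)
    nties = mask.sum(axis=axes, keepdims=True)
    res = out_data if keepdims else out_data.squeeze(axis=axes)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(x, mask * (g / nties))

    return Var(res, (x,), bw)


def maximum(a: Var, b: Var) -> Var:
    out_data = np.maximum(a.data, b.data)
    amask = a.data >= b.data

    def bw(g):
        _accum(a, _unbroadcast(g * amask, a.data.shape))
        _accum(b, _unbroadcast(g * (~amask), b.data.shape))

    return Var(out_data, (a, b), bw)


def reshape(x: Var, shape) -> Var:
    out = Var(x.data.reshape(shape), (x,))
    out.backward_fn = lambda g: _accum(x, g.reshape(x.data.shape))
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on raw arrays (inference path)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Var, y: np.ndarray,
                          sample_weight: np.ndarray | None = None) -> Var:
    """Mean (weighted) categorical cross-entropy from integer labels.

    The loss is accumulated in float64 so that sums of several head losses
    compare exactly against the recomputed per-head values.
    """
    y = np.asarray(y, dtype=np.intp)
    n, k = logits.data.shape
    p = softmax(logits.data)
    eps = 1e-12
    nll = -np.log(p[np.arange(n), y] + eps)
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
    loss = float((nll * w).sum() / n)
    out = Var(np.float32(loss), (logits,))

    def bw(g):
        gl = (p.copy())
        gl[np.arange(n), y] -= 1.0
        gl *= (w / n)[:, None]
        _accum(logits, (g * gl).astype(np.float32))

    out.backward_fn = bw
    # keep the float64 value accessible for loss bookkeeping
    out.name = "loss"
    out.data = np.asarray(loss)  # float64 scalar
    return out


def add_n(xs: list[Var]) -> Var:
    """Sum of scalar losses, accumulated in float64 so that the total is
    exactly the arithmetic sum of the parts."""
    total = np.float64(0.0)
    for x in xs:
        total = total + np.asarray(x.data, dtype=np.float64)
    out = Var(np.asarray(total, dtype=np.float32), tuple(xs))

    def bw(g):
        for x in xs:
            _accum(x, _unbroadcast(g, np.shape(x.data)))

    out.backward_fn = bw
    out.data = np.asarray(total)  # float64 view for bookkeeping
    return out


def backward(root: Var, seed: float = 1.0) -> None:
    """Reverse-mode sweep populating ``.grad`` on every reachable node."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.full_like(np.asarray(root.data, dtype=np.float32), seed)
    for node in reversed(topo):
        if node.backward_fn is not None and node.grad is not None:
            node.backward_fn(node.grad)
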