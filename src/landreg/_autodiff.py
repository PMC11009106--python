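"""Compact reverse-mode automatic differentiation on numpy arrays.

The training regimes differentiate a composite graph: convolutional
heatmap network -> spatial soft-argmax -> thin-plate-spline linear solve
-> bilinear image warp -> multiscale structural-similarity loss.  This
module provides exactly the operator set that graph needs (elementwise
arithmetic, matmul, conv2d, pooling, softmax, linear solve, bilinear
grid sampling) with analytic gradients, plus an Adam optimizer.

Arrays are float64 throughout.  Graphs are built only when an input has
``requires_grad=True``; inference-mode calls carry no bookkeeping cost
beyond the array work itself.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "as_tensor", "Adam"]

_LN2 = math.log(2.0)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        track = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- unary math -----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def log2(self):
        return self.log() * (1.0 / _LN2)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % len(shape) for a in axes)
                gg = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(gg, shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- n-ary / structural ops ---------------------------------------------------


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tensors, backward
    )


def where(cond, a, b) -> Tensor:
    """Select with a constant (non-differentiated) boolean condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (constant) max for numerical stability; softmax is
    # shift-invariant so the gradient is unaffected
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def solve(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable ``x = a^{-1} b`` for square ``a`` (b may be a matrix)."""
    a, b = as_tensor(a), as_tensor(b)
    x = np.linalg.solve(a.data, b.data)

    def backward(g):
        gb = np.linalg.solve(a.data.T, g)
        if b.requires_grad:
            b._accum(gb)
        if a.requires_grad:
            a._accum(-gb @ x.T)

    return Tensor._make(x, (a, b), backward)


def pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the last two axes by ``p`` on each side."""
    if p == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]

    def backward(g):
        if x.requires_grad:
            sl = [slice(None)] * (x.ndim - 2) + [slice(p, -p), slice(p, -p)]
            x._accum(g[tuple(sl)])

    return Tensor._make(np.pad(x.data, widths), (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    xp = pad2d(x, padding)
    xpd = xp.data
    n, c, hp, wp = xpd.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ho, wo = hp - kh + 1, wp - kw + 1
    out = np.zeros((n, ho, wo, o), dtype=np.float64)
    for u in range(kh):
        for v in range(kw):
            # (N,C,ho,wo) x (O,C) -> (N,ho,wo,O)
            out += np.tensordot(
                xpd[:, :, u : u + ho, v : v + wo], w.data[:, :, u, v], axes=([1], [1])
            )
    out = np.moveaxis(out, 3, 1)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data[None, :, None, None]
        parents = (xp, w, b)
    else:
        parents = (xp, w)

    def backward(g):
        # g: (N, O, ho, wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gm = np.moveaxis(g, 1, 3)  # (N, ho, wo, O)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for u in range(kh):
                for v in range(kw):
                    # (O, C) from (N,ho,wo,O) and (N,C,ho,wo)
                    gw[:, :, u, v] = np.tensordot(
                        gm, xpd[:, :, u : u + ho, v : v + wo], axes=([0, 1, 2], [0, 2, 3])
                    )
            w._accum(gw)
        if xp.requires_grad:
            gx = np.zeros_like(xpd)
            for u in range(kh):
                for v in range(kw):
                    gx[:, :, u : u + ho, v : v + wo] += np.tensordot(
                        gm, w.data[:, :, u, v], axes=([3], [0])
                    ).transpose(0, 3, 1, 2)
            xp._accum(gx)

    return Tensor._make(out, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {(h, w)} not divisible by pool {k}")
    out = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(gx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)
    n, c, h, w = x.shape

    def backward(g):
        if x.requires_grad:
            gx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(gx)

    return Tensor._make(out, (x,), backward)


def grid_sample(img: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling of ``img`` (C, H, W) at ``coords`` (P, 2) = (x, y).

    Pixel centers sit at integer coordinates; samples outside the image
    evaluate to 0 (black background).  Differentiable in both the image
    values and the sample coordinates.
    """
    img, coords = as_tensor(img), as_tensor(coords)
    c, h, w = img.shape
    xy = coords.data
    x, y = xy[:, 0], xy[:, 1]
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx, fy = x - x0, y - y0

    vals = []  # corner pixel values (C, P), zero outside
    valid = []
    for dy in (0, 1):
        for dx in (0, 1):
            xi, yi = x0 + dx, y0 + dy
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            v = img.data[:, np.clip(yi, 0, h - 1), np.clip(xi, 0, w - 1)]
            vals.append(np.where(ok[None, :], v, 0.0))
            valid.append(ok)
    w00 = (1 - fx) * (1 - fy)
    w01 = fx * (1 - fy)
    w10 = (1 - fx) * fy
    w11 = fx * fy
    weights = [w00, w01, w10, w11]
    out = sum(v * wt[None, :] for v, wt in zip(vals, weights))

    def backward(g):
        # g: (C, P)
        if coords.requires_grad:
            dwx = [-(1 - fy), (1 - fy), -fy, fy]
            dwy = [-(1 - fx), -fx, (1 - fx), fx]
            gx = sum((g * v).sum(axis=0) * d for v, d in zip(vals, dwx))
            gy = sum((g * v).sum(axis=0) * d for v, d in zip(vals, dwy))
            gc = np.stack([gx, gy], axis=1)
            coords._accum(gc)
        if img.requires_grad:
            gi = np.zeros_like(img.data)
            for v, wt, ok, (dy, dx) in zip(
                vals, weights, valid, [(0, 0), (0, 1), (1, 0), (1, 1)]
            ):
                xi = np.clip(x0 + dx, 0, w - 1)
                yi = np.clip(y0 + dy, 0, h - 1)
                contrib = np.where(ok[None, :], g * wt[None, :], 0.0)
                np.add.at(gi, (slice(None), yi, xi), contrib)
            img._accum(gi)

    return Tensor._make(out, (img, coords), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
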