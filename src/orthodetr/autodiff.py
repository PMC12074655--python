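"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for every trainable module in the package:
a tape-free define-by-run graph of :class:`Tensor` nodes, each holding a
float64 ``ndarray`` and a backward closure. The op set is exactly what the
detector needs — dense algebra, 2-D convolution via im2col, normalisation,
pointwise nonlinearities, softmax, and differentiable bilinear grid
sampling — plus an Adam optimiser.

Gradients are accumulated (summed) into ``Tensor.grad``; broadcasting in
forward ops is undone by summing the gradient over the broadcast axes.
All arithmetic is float64: the package favours exactness of gradient
checks over speed, and the models here are desk-scale.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), name: str | None = None):
        self.data = _as_array(data)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev = _prev
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'}{tag})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            # always copy: g may alias another node's grad buffer
            self.grad = np.array(g)
        else:
            self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else _as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw() -> None:
            self._accumulate(_unbroadcast(out.grad, self.shape))
            other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw() -> None:
            self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw() -> None:
            self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            other._accumulate(_unbroadcast(-out.grad * self.data / other.data ** 2, other.shape))

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        return matmul(self, other)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw() -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accumulate(g)

        out._backward = _bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad.transpose(inv))
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw() -> None:
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise -----------------------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * (1.0 - t * t))
        return out

    def clip_min(self, lo: float) -> "Tensor":
        out = Tensor(np.maximum(self.data, lo), _prev=(self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > lo))
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product supporting numpy's batched matmul broadcasting."""
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def _bw() -> None:
        ga = out.grad @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ out.grad
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw() -> None:
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accumulate(g)

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def _bw() -> None:
        for i, t in enumerate(tensors):
            t._accumulate(np.take(out.grad, i, axis=axis))

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def _bw() -> None:
        g = out.grad
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = _bw
    return out


def softplus(x: Tensor) -> Tensor:
    # numerically stable log(1 + e^x)
    d = np.logaddexp(0.0, x.data)
    out = Tensor(d, _prev=(x,))
    out._backward = lambda: x._accumulate(out.grad / (1.0 + np.exp(-x.data)))
    return out


def bce_with_logits(logits: Tensor, targets: Array) -> Tensor:
    """Mean binary cross-entropy on raw logits; targets is a constant array."""
    t = _as_array(targets)
    return (softplus(logits) - logits * Tensor(t)).mean()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis; built from primitives so gradients come free."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xhat = xc * ((var + eps) ** -0.5)
    return xhat * gamma + beta


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation of a (b, c, h, w) map over (b, h, w).

    Always uses batch statistics — the models here are trained and probed on
    fixed small batches, so no running-average inference mode is kept.
    Fused single-op implementation with an analytic backward pass.
    """
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gq = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gq + beta.data.reshape(1, -1, 1, 1), _prev=(x, gamma, beta))

    def _bw() -> None:
        g = out.grad
        gamma._accumulate((g * xhat).sum(axis=axes))
        beta._accumulate(g.sum(axis=axes))
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(gq * inv * (g - gm - xhat * gxm))

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# conv2d via im2col
# ---------------------------------------------------------------------------

def _im2col(x: Array, kh: int, kw: int, stride: int, pad: int) -> tuple[Array, int, int]:
    b, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    sb, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return cols.reshape(b, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: Array, x_shape: tuple, kh: int, kw: int, stride: int, pad: int) -> Array:
    b, c, h, w = x_shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), weight shape (co, ci, kh, kw)."""
    co, ci, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)        # (b, ci*kh*kw, L)
    cols = np.ascontiguousarray(cols)
    wmat = weight.data.reshape(co, ci * kh * kw)
    y = np.matmul(wmat, cols)                                  # (b, co, L)
    if bias is not None:
        y = y + bias.data.reshape(1, co, 1)
    b = x.shape[0]
    out = Tensor(y.reshape(b, co, ho, wo), _prev=(x, weight) + ((bias,) if bias is not None else ()))

    def _bw() -> None:
        g = out.grad.reshape(b, co, ho * wo)
        gw = np.tensordot(g, cols, axes=([0, 2], [0, 2])).reshape(weight.shape)
        weight._accumulate(gw)
        gcols = np.matmul(wmat.T, g)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2)))

    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of a (b, c, h, w) map."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y, _prev=(x,))
    b, c, h, w = x.shape

    def _bw() -> None:
        g = out.grad.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accumulate(g)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# differentiable bilinear grid sampling
# ---------------------------------------------------------------------------

def _scatter_add(gx: Array, yy: Array, xx: Array, val: Array) -> None:
    # gx: (b, c, h, w); yy/xx: (b, n); val: (b, n, c)
    b, c, h, w = gx.shape
    flat = gx.reshape(b, c, h * w)
    lin = yy * w + xx                        # (b, n)
    for bi in range(b):
        np.add.at(flat[bi], (slice(None), lin[bi]), val[bi].T)


def grid_sample(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling of feature map ``x`` (b, c, h, w) at normalised
    ``coords`` (b, n, 2) with (x, y) in [-1, 1]; (-1,-1) is the top-left pixel
    centre and (+1,+1) the bottom-right. Out-of-range coordinates are clamped
    to the border. Differentiable in both the feature map and the coordinates
    (almost everywhere; the integer lattice is measure zero).
    """
    b, c, h, w = x.shape
    n = coords.shape[1]
    px = (coords.data[..., 0] + 1.0) * 0.5 * (w - 1) if w > 1 else np.zeros((b, n))
    py = (coords.data[..., 1] + 1.0) * 0.5 * (h - 1) if h > 1 else np.zeros((b, n))
    px = np.clip(px, 0.0, w - 1)
    py = np.clip(py, 0.0, h - 1)
    x0 = np.clip(np.floor(px).astype(np.int64), 0, max(w - 2, 0))
    y0 = np.clip(np.floor(py).astype(np.int64), 0, max(h - 2, 0))
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (px - x0)
    fy = (py - y0)

    bidx = np.arange(b)[:, None]
    xcl = x.data.transpose(0, 2, 3, 1)       # (b, h, w, c)
    v00 = xcl[bidx, y0, x0]
    v01 = xcl[bidx, y0, x1]
    v10 = xcl[bidx, y1, x0]
    v11 = xcl[bidx, y1, x1]
    wx0, wx1 = (1 - fx)[..., None], fx[..., None]
    wy0, wy1 = (1 - fy)[..., None], fy[..., None]
    val = v00 * wy0 * wx0 + v01 * wy0 * wx1 + v10 * wy1 * wx0 + v11 * wy1 * wx1
    out = Tensor(val, _prev=(x, coords))

    inx = (coords.data[..., 0] > -1.0) & (coords.data[..., 0] < 1.0)
    iny = (coords.data[..., 1] > -1.0) & (coords.data[..., 1] < 1.0)

    def _bw() -> None:
        g = out.grad
        gx = np.zeros_like(x.data)
        _scatter_add(gx, y0, x0, g * wy0 * wx0)
        _scatter_add(gx, y0, x1, g * wy0 * wx1)
        _scatter_add(gx, y1, x0, g * wy1 * wx0)
        _scatter_add(gx, y1, x1, g * wy1 * wx1)
        x._accumulate(gx)
        dpx = (v01 - v00) * wy0 + (v11 - v10) * wy1
        dpy = (v10 - v00) * wx0 + (v11 - v01) * wx1
        gpx = (g * dpx).sum(axis=-1) * (0.5 * (w - 1) if w > 1 else 0.0) * inx
        gpy = (g * dpy).sum(axis=-1) * (0.5 * (h - 1) if h > 1 else 0.0) * iny
        coords._accumulate(np.stack([gpx, gpy], axis=-1))

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# parameters and optimiser
# ---------------------------------------------------------------------------

class Module:
    """Base for anything holding parameters; collects them recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[Array]:
        return [p.data for p in self.parameters()]


def _collect(v) -> Iterable[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)
    elif isinstance(v, dict):
        for item in v.values():
            yield from _collect(item)


def param(rng: np.random.Generator, *shape: int, scale: float | None = None,
          name: str | None = None) -> Tensor:
    """Kaiming-style initialised trainable tensor."""
    if scale is None:
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
        scale = math.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True, name=name)


def zeros_param(*shape: int, name: str | None = None) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True, name=name)


def ones_param(*shape: int, name: str | None = None) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True, name=name)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, din: int, dout: int, bias: bool = True):
        self.w = param(rng, din, dout, scale=math.sqrt(1.0 / max(din, 1)))
        self.b = zeros_param(dout) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Adam:
    """Adam with optional gradient clipping by global norm."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
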