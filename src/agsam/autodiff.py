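"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core of the package: a small, dependency-free tensor
graph supporting exactly the operations the segmentation models need --
2-D convolution (via im2col), pooling, bilinear resampling, batched matrix
products and softmax for attention, and elementwise arithmetic.  Gradients
are accumulated by a topological backward sweep, micrograd-style, but over
whole ``float32`` arrays rather than scalars.

Design notes
------------
* All tensors are ``float32``; single precision keeps full-scale forward
  passes (ResNet-50-shaped trunks, ViT-shaped encoders) inside CPU memory.
* ``requires_grad=False`` parameters still propagate gradients *through*
  themselves to their inputs -- freezing a module stops weight updates, it
  does not detach the graph.  This distinction is load-bearing for prompt
  learning through a frozen mask decoder.
* Bilinear resize is expressed as two 1-D interpolation matrices applied to
  the trailing axes, so its adjoint is exactly the transposed matrices.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "tensor",
    "concat",
    "stack",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph plumbing -------------------------------------------------------

    def _track(self, out: "Tensor", parents: Sequence["Tensor"],
               backward: Callable[[np.ndarray], None]) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)

        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS: graphs are deep (50+ conv layers) and recursion-limited
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            elif node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for p, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(p)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- elementwise arithmetic ----------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data)

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return self._track(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        return self._track(out, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data)

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return self._track(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.data / other.data)

        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.shape)))

        return self._track(out, (self, other), backward)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def pow(self, p: float):
        out = Tensor(self.data ** p)

        def backward(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return self._track(out, (self,), backward)

    __pow__ = pow

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g2, self.shape).copy()),)

        return self._track(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask)
        return self._track(out, (self,), lambda g: ((self, g * mask),))

    def exp(self):
        out = Tensor(np.exp(self.data))
        return self._track(out, (self,), lambda g: ((self, g * out.data),))

    def log(self):
        out = Tensor(np.log(self.data))
        return self._track(out, (self,), lambda g: ((self, g / self.data),))

    def sqrt(self):
        return self.pow(0.5)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((self, s * (g - dot)),)

        return self._track(out, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s)
        return self._track(out, (self,), lambda g: ((self, g * s * (1 - s)),))

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape))
        return self._track(out, (self,),
                           lambda g: ((self, g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        return self._track(out, (self,),
                           lambda g: ((self, g.transpose(inv)),))

    # -- linear algebra -------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = _wrap(other)
        out = Tensor(np.matmul(self.data, other.data))

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return self._track(out, (self, other), backward)

    __matmul__ = matmul

    # -- spatial ops ----------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1):
        """2-D cross-correlation over [N, C, H, W] with [O, C, kh, kw]."""
        x, w = self.data, weight.data
        n, c, h, wdt = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
        eh = (kh - 1) * dilation + 1
        ew = (kw - 1) * dilation + 1
        oh = (h + 2 * padding - eh) // stride + 1
        ow = (wdt + 2 * padding - ew) // stride + 1

        cols = _im2col(x, kh, kw, stride, padding, dilation)  # [N, C*kh*kw, oh*ow]
        wmat = w.reshape(o, -1)
        out_data = np.matmul(wmat, cols).reshape(n, o, oh, ow)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, o, 1, 1)
        out = Tensor(out_data)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gmat = g.reshape(n, o, oh * ow)
            gw = np.einsum("nop,ncp->oc", gmat, cols,
                           optimize=True).reshape(w.shape)
            gcols = np.matmul(wmat.T, gmat)
            gx = _col2im(gcols, x.shape, kh, kw, stride, padding, dilation)
            grads = [(self, gx), (weight, gw)]
            if bias is not None:
                grads.append((bias, g.sum(axis=(0, 2, 3))))
            return tuple(grads)

        return self._track(out, parents, backward)

    def avg_pool2d(self, k: int):
        """Non-overlapping average pooling; spatial dims must divide by k."""
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {k}")
        r = self.data.reshape(n, c, h // k, k, w // k, k)
        out = Tensor(r.mean(axis=(3, 5)))

        def backward(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            return ((self, gx),)

        return self._track(out, (self,), backward)

    def max_pool2d(self, k: int, stride: int | None = None, padding: int = 0):
        stride = stride or k
        x = self.data
        n, c, h, w = x.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                           (padding, padding)), constant_values=-np.inf)
        hp, wp = x.shape[2], x.shape[3]
        oh = (hp - k) // stride + 1
        ow = (wp - k) // stride + 1
        strides = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, (n, c, oh, ow, k, k),
            (strides[0], strides[1], strides[2] * stride,
             strides[3] * stride, strides[2], strides[3]))
        flat = win.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0])

        def backward(g):
            gx = np.zeros((n, c, hp, wp), dtype=np.float32)
            oy, ox = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
            ky, kx = idx // k, idx % k
            rows = oy[None, None] * stride + ky
            colsx = ox[None, None] * stride + kx
            nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            np.add.at(gx, (nn[..., None, None], cc[..., None, None],
                           rows, colsx), g)
            if padding:
                gx = gx[:, :, padding:hp - padding, padding:wp - padding]
            return ((self, gx),)

        return self._track(out, (self,), backward)

    def resize_bilinear(self, out_h: int, out_w: int):
        """Bilinear resample of the trailing two axes (align_corners=False)."""
        h, w = self.shape[-2], self.shape[-1]
        ah = _interp_matrix(h, out_h)
        aw = _interp_matrix(w, out_w)
        out_data = np.tensordot(np.tensordot(self.data, ah.T, axes=([-2], [0])),
                                aw.T, axes=([-2], [0]))
        # tensordot moved axes: result has shape [..., out_h, out_w] already
        out = Tensor(out_data)

        def backward(g):
            gx = np.tensordot(np.tensordot(g, ah, axes=([-2], [0])),
                              aw, axes=([-2], [0]))
            return ((self, gx),)

        return self._track(out, (self,), backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 2):
        """Transposed convolution as zero-stuffing followed by conv2d.

        ``weight`` has layout [C_in, C_out, k, k]; output side =
        (in-1)*stride + k with no output padding.
        """
        n, c, h, w = self.shape
        cin, cout, kh, kw = weight.shape
        if cin != c:
            raise ValueError("conv_transpose2d channel mismatch")
        # zero-stuff
        hs = (h - 1) * stride + 1
        ws = (w - 1) * stride + 1
        stuffed = _zero_stuff(self, stride, hs, ws)
        wflip = weight.transpose(1, 0, 2, 3)
        wflip = Tensor._flip_kernel(wflip)
        return stuffed.conv2d(wflip, bias, stride=1, padding=kh - 1)

    @staticmethod
    def _flip_kernel(w: "Tensor") -> "Tensor":
        out = Tensor(w.data[:, :, ::-1, ::-1].copy())

        def backward(g):
            return ((w, g[:, :, ::-1, ::-1].copy()),)

        return w._track(out, (w,), backward)


def _zero_stuff(t: Tensor, stride: int, hs: int, ws: int) -> Tensor:
    n, c, h, w = t.shape
    data = np.zeros((n, c, hs, ws), dtype=np.float32)
    data[:, :, ::stride, ::stride] = t.data
    out = Tensor(data)

    def backward(g):
        return ((t, g[:, :, ::stride, ::stride].copy()),)

    return t._track(out, (t,), backward)


# -- free functions ------------------------------------------------------------


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    return tensors[0]._track(out, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.reshape(t.shape)) for t, p in zip(tensors, parts))

    return tensors[0]._track(out, tuple(tensors), backward)


# -- helpers -------------------------------------------------------------------


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _axis_size(shape: tuple[int, ...], axis) -> int:
    if isinstance(axis, int):
        return shape[axis]
    n = 1
    for a in axis:
        n *= shape[a]
    return n


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int,
            dilation: int) -> np.ndarray:
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding),
                       (padding, padding)))
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    oh = (x.shape[2] - eh) // stride + 1
    ow = (x.shape[3] - ew) // stride + 1
    s = x.strides
    win = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow),
        (s[0], s[1], s[2] * dilation, s[3] * dilation,
         s[2] * stride, s[3] * stride))
    return np.ascontiguousarray(win).reshape(n, c * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int,
            stride: int, padding: int, dilation: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    oh = (hp - eh) // stride + 1
    ow = (wp - ew) // stride + 1
    x = np.zeros((n, c, hp, wp), dtype=np.float32)
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    for iy in range(kh):
        y0 = iy * dilation
        for ix in range(kw):
            x0 = ix * dilation
            x[:, :, y0:y0 + stride * oh:stride,
              x0:x0 + stride * ow:stride] += cols6[:, :, iy, ix]
    if padding:
        x = x[:, :, padding:hp - padding, padding:wp - padding]
    return x


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix [n_out, n_in]."""
    if n_in == n_out:
        return np.eye(n_in, dtype=np.float32)
    a = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        a[i, lo] += 1.0 - frac
        a[i, hi] += frac
    return a
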