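"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: each :class:`Tensor` wraps an ndarray and
remembers the operation that produced it. ``Tensor.backward()`` walks the
graph in reverse topological order and accumulates gradients into every
leaf with ``requires_grad=True``. Only the operations the network needs are
implemented; each op's backward is exact (no approximations), which the
finite-difference tests rely on.
"""

from __future__ import annotations

import itertools
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph -------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad = self.grad + g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: ((self, -g),))

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p

        def bwd(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            return (
                (self, g @ other.data.swapaxes(-1, -2)),
                (other, self.data.swapaxes(-1, -2) @ g),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _backward=lambda g: ((self, g.reshape(orig)),),
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            out_b = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == out_b).astype(self.data.dtype)
            count = mask.sum(axis=axis, keepdims=True)
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            return ((self, mask / count * g),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0)

        def bwd(g):
            return ((self, g * (self.data > 0)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bwd(g):
            return ((self, g / self.data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bwd(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only inside the range."""
        out_data = np.clip(self.data, lo, hi)

        def bwd(g):
            inside = (self.data >= lo) & (self.data <= hi)
            return ((self, g * inside),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# Spatial operations (3-D). Inputs are (B, C, D, H, W).
# ---------------------------------------------------------------------------

def _conv_out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor],
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped 3-D convolution (cross-correlation, PyTorch convention).

    ``w`` has shape (C_out, C_in // groups, k, k, k). Implemented as a loop
    over kernel offsets, each a batched channel contraction over strided
    views — memory-light and exact.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, D, H, W = x.shape
    Cout, Cing, kd, kh, kw = w.shape
    if Cin != Cing * groups or Cout % groups:
        raise ValueError(
            f"channel mismatch: x has {Cin} channels, weight expects "
            f"{Cing * groups} (groups={groups}, C_out={Cout})"
        )
    s, p, dil = stride, padding, dilation
    Do, Ho, Wo = (_conv_out_size(n, k, s, p, dil) for n, k in ((D, kd), (H, kh), (W, kw)))
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    G, Og = groups, Cout // groups
    xg = xp.reshape(B, G, Cing, *xp.shape[2:])
    wg = w.data.reshape(G, Og, Cing, kd, kh, kw)
    L = Do * Ho * Wo
    y = np.zeros((B, G, Og, L), dtype=np.result_type(x.data, w.data))
    offs = list(itertools.product(range(kd), range(kh), range(kw)))

    def view(arr, i, j, k):
        return arr[
            :, :, :,
            i * dil : i * dil + s * (Do - 1) + 1 : s,
            j * dil : j * dil + s * (Ho - 1) + 1 : s,
            k * dil : k * dil + s * (Wo - 1) + 1 : s,
        ]

    for i, j, k in offs:
        xs = view(xg, i, j, k).reshape(B, G, Cing, L)
        y += np.matmul(wg[None, :, :, :, i, j, k], xs)
    out_data = y.reshape(B, Cout, Do, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gy = g.reshape(B, G, Og, L)
        gxp = np.zeros_like(xp)
        gxg = gxp.reshape(B, G, Cing, *xp.shape[2:])
        gw = np.zeros_like(w.data).reshape(G, Og, Cing, kd, kh, kw)
        for i, j, k in offs:
            xs = view(xg, i, j, k).reshape(B, G, Cing, L)
            gw[:, :, :, i, j, k] = np.matmul(gy, xs.swapaxes(-1, -2)).sum(axis=0)
            gx_off = np.matmul(wg[None, :, :, :, i, j, k].swapaxes(-1, -2), gy)
            view(gxg, i, j, k)[...] += gx_off.reshape(B, G, Cing, Do, Ho, Wo)
        gx = gxp[:, :, p : p + D, p : p + H, p : p + W] if p else gxp
        grads = [(x, gx), (w, gw.reshape(w.shape))]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    return Tensor(out_data, _parents=parents, _backward=bwd)


def maxpool3d_2(x: Tensor) -> Tensor:
    """2×2×2 max pooling with stride 2 (dims must be even)."""
    x = as_tensor(x)
    B, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d_2 needs even spatial dims, got {(D, H, W)}")
    xr = x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out_data = xr.max(axis=(3, 5, 7))

    def bwd(g):
        mask = (xr == out_data[:, :, :, None, :, None, :, None]).astype(x.data.dtype)
        count = mask.sum(axis=(3, 5, 7), keepdims=True)
        gx = mask / count * g[:, :, :, None, :, None, :, None]
        return ((x, gx.reshape(x.shape)),)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def _upsample_matrix(n: int, dtype) -> np.ndarray:
    """Dense (2n, n) matrix of ×2 linear interpolation, half-pixel centers."""
    m = np.zeros((2 * n, n), dtype=dtype)
    for o in range(2 * n):
        c = (o + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(c))
        t = c - i0
        i0c, i1c = np.clip(i0, 0, n - 1), np.clip(i0 + 1, 0, n - 1)
        m[o, i0c] += 1.0 - t
        m[o, i1c] += t
    return m


def upsample_trilinear_2(x: Tensor) -> Tensor:
    """Trilinear ×2 upsampling (align_corners=False convention)."""
    x = as_tensor(x)
    B, C, D, H, W = x.shape
    dt = x.data.dtype if np.issubdtype(x.data.dtype, np.floating) else np.float64
    Md, Mh, Mw = (_upsample_matrix(n, dt) for n in (D, H, W))

    def apply(arr, md, mh, mw):
        out = np.einsum("od,bcdhw->bcohw", md, arr, optimize=True)
        out = np.einsum("ph,bcdhw->bcdpw", mh, out, optimize=True)
        return np.einsum("qw,bcdhw->bcdhq", mw, out, optimize=True)

    out_data = apply(x.data, Md, Mh, Mw)

    def bwd(g):
        return ((x, apply(g, Md.T, Mh.T, Mw.T)),)

    return Tensor(out_data, _parents=(x,), _backward=bwd)
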