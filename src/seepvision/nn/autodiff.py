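"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine in the micrograd tradition, but with vectorized array
ops (conv2d via im2col + BLAS matmul, instance normalisation, nearest
upsampling) — exactly the primitives a compact image-translation GAN
needs.  float32 throughout.  Gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "im2col", "col2im"]


def _as_f32(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    # note: ascontiguousarray would promote 0-d scalars to shape (1,)
    if arr.ndim and not arr.flags["C_CONTIGUOUS"]:
        arr = np.ascontiguousarray(arr)
    return arr


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free the closure so intermediate buffers can be collected
                node._backward = None
                node._parents = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def square(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * (2.0 * a.data))

        return Tensor._result(a.data * a.data, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._result(np.abs(a.data), (a,), backward)

    # -- reductions --------------------------------------------------------

    def mean(self):
        a = self
        n = a.data.size

        def backward(g):
            if a.requires_grad:
                a._accum(np.full_like(a.data, float(g) / n))

        return Tensor._result(a.data.mean(), (a,), backward)

    def sum(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(np.full_like(a.data, float(g)))

        return Tensor._result(a.data.sum(), (a,), backward)

    # -- activations -------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        scale = np.where(mask, np.float32(1.0), np.float32(slope))

        def backward(g):
            if a.requires_grad:
                a._accum(g * scale)

        return Tensor._result(a.data * scale, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data * out_data))

        return Tensor._result(out_data, (a,), backward)

    # -- structured ops ----------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, pad: int = 0):
        """2-D convolution (cross-correlation), NCHW x (Co,Ci,kh,kw)."""
        a, w, b = self, weight, bias
        x = a.data
        if pad > 0:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        n, ci, H, W = x.shape
        co, ci_w, kh, kw = w.data.shape
        assert ci == ci_w, f"channel mismatch {ci} vs {ci_w}"
        cols = im2col(x, kh, kw, stride)  # (n, ci*kh*kw, L)
        ho = (H - kh) // stride + 1
        wo = (W - kw) // stride + 1
        wmat = w.data.reshape(co, -1)
        out = np.einsum("ok,nkl->nol", wmat, cols, optimize=True)
        out = out.reshape(n, co, ho, wo) + b.data.reshape(1, co, 1, 1)

        def backward(g):
            gmat = g.reshape(n, co, -1)  # (n, co, L)
            if b.requires_grad:
                b._accum(gmat.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.einsum("nol,nkl->ok", gmat, cols, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            if a.requires_grad:
                gcols = np.einsum("ok,nol->nkl", wmat, gmat, optimize=True)
                gx = col2im(gcols, (n, ci, H, W), kh, kw, stride)
                if pad > 0:
                    gx = gx[:, :, pad:-pad, pad:-pad]
                a._accum(gx)

        return Tensor._result(out, (a, w, b), backward)

    def instance_norm(self, eps: float = 1e-5):
        """Per-sample per-channel normalisation, no affine parameters."""
        a = self
        x = a.data
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (x - mu) * inv

        def backward(g):
            if a.requires_grad:
                gm = g.mean(axis=(2, 3), keepdims=True)
                gym = (g * y).mean(axis=(2, 3), keepdims=True)
                a._accum(inv * (g - gm - y * gym))

        return Tensor._result(y, (a,), backward)

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling."""
        a = self
        out = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            if a.requires_grad:
                n, c, h2, w2 = g.shape
                gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                a._accum(gx)

        return Tensor._result(out, (a,), backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Unfold (n, c, H, W) into (n, c*kh*kw, L) patch columns."""
    n, c, H, W = x.shape
    ho = (H - kh) // stride + 1
    wo = (W - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view.reshape(n, c * kh * kw, ho * wo))


def col2im(
    cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int
) -> np.ndarray:
    """Fold patch-column gradients back to the input shape (scatter-add)."""
    n, c, H, W = x_shape
    ho = (H - kh) // stride + 1
    wo = (W - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    return x
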