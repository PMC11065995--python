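"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each op records a closure that
propagates the upstream gradient to its inputs. Convolution, pooling,
upsampling and batch normalisation are primitives with hand-written
backward passes (composing them from elementwise ops would be far too
slow on CPU); everything else is generic elementwise algebra with
broadcasting-aware gradient reduction.

Feature maps are channels-last (B, H, W, C): convolution is then a sum of
kernel-tap shifts, each a plain GEMM over the channel axis, which is the
fastest dense formulation numpy offers on one CPU core. All convolutions
are stride-1 "same"; spatial down/upsampling is explicit 2x2 max-pooling
and nearest-neighbour upsampling.

Gradients are accumulated in the dtype of the tensor they belong to:
float32 for network training, float64 when a float64 tensor is used (as in
finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "upsample2x", "batchnorm2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            # copy: g may be a view into another buffer or broadcast
            self.grad = np.array(g, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(g, self.data.shape).astype(self.data.dtype)
        else:
            self.grad += g

    def _accum_owned(self, g):
        """Like _accum but takes ownership of a freshly allocated array."""
        if self.grad is None and g.dtype == self.data.dtype and g.shape == self.data.shape:
            self.grad = g
        else:
            self._accum(g)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- basic algebra ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data + o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self + (-o)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data * o.data

        def bwd(g):
            if self.requires_grad:
                self._accum_owned(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum_owned(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data / o.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                # subgradient 0 at the origin: avoids inf/NaN on exact zeros
                # (e.g. an all-background batch in the MCC loss)
                positive = out_data > 0
                safe = np.where(positive, out_data, 1.0)
                self._accum(np.where(positive, g * 0.5 / safe, 0.0))

        return Tensor._make(out_data, (self,), bwd)

    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(), (self,), bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor._make(self.data.mean(), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum_owned(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accum_owned(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)


# -- structural / conv primitives -----------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int, groups: int = 1) -> Tensor:
    """Stride-1 'same' 2D convolution on channels-last maps.

    ``x`` is (B, H, W, Cin); ``w`` is (Cout, Cin//groups, kh, kw). Computed
    as a sum over kernel taps of shifted GEMMs; grouped and depthwise cases
    are specialised.
    """
    xd, wd = x.data, w.data
    B, H, W, C = xd.shape
    Cout, Cg, kh, kw = wd.shape
    G = groups
    Og = Cout // G
    p = padding
    xp = np.pad(xd, ((0, 0), (p, p), (p, p), (0, 0))) if p else xd
    Hp, Wp = xp.shape[1], xp.shape[2]
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    depthwise = (G > 1 and G == C and Cg == 1 and Cout == C)
    grouped = G > 1 and not depthwise
    if grouped:
        # expand block-diagonal grouped weights to dense (Cout, Cin, kh, kw):
        # trades G-fold redundant flops for one contiguous GEMM per tap,
        # which is much faster than channel-sliced GEMMs on CPU
        wdense = np.zeros((Cout, C, kh, kw), dtype=wd.dtype)
        for g_ in range(G):
            wdense[g_ * Og:(g_ + 1) * Og, g_ * Cg:(g_ + 1) * Cg] = wd[g_ * Og:(g_ + 1) * Og]
    else:
        wdense = wd
    out = np.zeros((B, Ho, Wo, Cout), dtype=xd.dtype)
    if depthwise:
        for i in range(kh):
            for j in range(kw):
                out += xp[:, i:i + Ho, j:j + Wo, :] * wd[:, 0, i, j]
    else:
        for i in range(kh):
            for j in range(kw):
                out += xp[:, i:i + Ho, j:j + Wo, :] @ wdense[:, :, i, j].T
    if b is not None:
        out += b.data

    def bwd(g):
        g = np.ascontiguousarray(g, dtype=xd.dtype)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            dw = np.zeros_like(wd)
            if depthwise:
                for i in range(kh):
                    for j in range(kw):
                        dw[:, 0, i, j] = (g * xp[:, i:i + Ho, j:j + Wo, :]).sum(axis=(0, 1, 2))
            else:
                for i in range(kh):
                    for j in range(kw):
                        dwij = np.tensordot(g, xp[:, i:i + Ho, j:j + Wo, :], axes=([0, 1, 2], [0, 1, 2]))
                        if grouped:
                            for g_ in range(G):
                                dw[g_ * Og:(g_ + 1) * Og, :, i, j] = dwij[g_ * Og:(g_ + 1) * Og, g_ * Cg:(g_ + 1) * Cg]
                        else:
                            dw[:, :, i, j] = dwij
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            if depthwise:
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + Ho, j:j + Wo, :] += g * wd[:, 0, i, j]
            else:
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + Ho, j:j + Wo, :] += g @ wdense[:, :, i, j]
            x._accum_owned(np.ascontiguousarray(dxp[:, p:Hp - p, p:Wp - p, :]) if p else dxp)

    return Tensor._make(out, (x, w, b) if b is not None else (x, w), bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    B, H, W, C = x.data.shape
    r = x.data.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    r = np.ascontiguousarray(r).reshape(B, H // 2, W // 2, C, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if x.requires_grad:
            d = np.zeros((B, H // 2, W // 2, C, 4), dtype=x.data.dtype)
            np.put_along_axis(d, idx[..., None], g[..., None], axis=-1)
            d = np.ascontiguousarray(d.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3))
            x._accum_owned(d.reshape(B, H, W, C))

    return Tensor._make(out_data, (x,), bwd)


def upsample2x(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bwd(g):
        if x.requires_grad:
            B, H, W, C = x.data.shape
            x._accum_owned(g.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)))

    return Tensor._make(out_data, (x,), bwd)


def instancenorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance normalisation over (H, W) per sample and channel, with affine.

    Statistics are per-sample, so inference is deterministic and identical
    to training behaviour (no running-stats gap), and per-scanner contrast
    shifts are normalised away within each slice.
    """
    mean = x.data.mean(axis=(1, 2), keepdims=True)
    xhat = x.data - mean
    var = np.mean(np.square(xhat), axis=(1, 2), keepdims=True)
    std = np.sqrt(var + eps)
    xhat /= std
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 1, 2)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gs = gamma.data / std
            gm = g.mean(axis=(1, 2), keepdims=True)
            gxm = (g * xhat).mean(axis=(1, 2), keepdims=True)
            d = xhat * gxm
            d += gm
            np.subtract(g, d, out=d)
            d *= gs
            x._accum_owned(d)

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (B, H, W) for channels-last maps."""
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(x.data.dtype)
    xhat = (x.data - mean.astype(x.data.dtype)) / std
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 1, 2)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gs = gamma.data / std
            if training:
                gm = g.mean(axis=(0, 1, 2))
                gxm = (g * xhat).mean(axis=(0, 1, 2))
                d = xhat * gxm
                d += gm
                np.subtract(g, d, out=d)
                d *= gs
                x._accum_owned(d)
            else:
                x._accum_owned(gs * g)

    return Tensor._make(out_data, (x, gamma, beta), bwd)
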