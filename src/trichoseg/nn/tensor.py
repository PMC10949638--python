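"""A small reverse-mode autodiff engine on numpy arrays.

Coarse-grained tape: each node is a whole layer-level operation (convolution,
batch norm, pooling, ...) with a hand-written vector-Jacobian product, so the
Python overhead per training step stays negligible and all heavy lifting is
BLAS matrix multiplication.

Layout is channels-last, (N, H, W, C).  Convolution avoids ``im2col``
entirely: a kxk convolution is computed as k^2 pointwise GEMMs on the
contiguous padded frame with shifted accumulation, which keeps every matrix
product on contiguous memory (the strided-window approach spends more time
copying windows than multiplying them).

Only what the segmentation models need is implemented; this is not a general
framework.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "add",
    "mul",
    "concat",
    "relu",
    "silu",
    "sigmoid",
    "log",
    "power",
    "clip",
    "tsum",
    "tmean",
    "conv2d",
    "batch_norm",
    "max_pool2d",
    "global_avg_pool",
    "upsample_nearest",
]


class Tensor:
    """An array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ) -> None:
        data = np.asarray(data)
        # float32 by default; float64 inputs keep full precision (used by the
        # scalar loss/metric API)
        self.data = data if data.dtype == np.float64 else data.astype(np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Reverse-mode sweep from this tensor (typically a scalar loss)."""
        topo: List[Tensor] = []
        seen = set()
        # iterative post-order topological sort
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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

        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # convenience arithmetic with constants and tensors
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def constant(x) -> Tensor:
    return _as_tensor(x)


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x), the smooth gating used by efficiency-oriented nets."""
    s = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * s

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * (s + x.data * s * (1.0 - s)))

    return Tensor(out_data, parents=(x,), backward=backward)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor(out_data, parents=(x,), backward=backward)


def power(x: Tensor, exponent: float) -> Tensor:
    out_data = x.data**exponent

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * exponent * x.data ** (exponent - 1.0))

    return Tensor(out_data, parents=(x,), backward=backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the active range."""
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def tsum(x: Tensor) -> Tensor:
    out_data = np.array(x.data.sum(dtype=np.float64), dtype=x.data.dtype)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def tmean(x: Tensor) -> Tensor:
    n = x.data.size
    out_data = np.array(x.data.mean(dtype=np.float64), dtype=x.data.dtype)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / n, x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# spatial ops (channels-last)


def _conv_geometry(h: int, w: int, k: int, stride: int, padding: int, dilation: int):
    k_eff = (k - 1) * dilation + 1
    ho = (h + 2 * padding - k_eff) // stride + 1
    wo = (w + 2 * padding - k_eff) // stride + 1
    return ho, wo


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, NHWC layout, square kernels.

    ``w`` has shape (out_ch, in_ch // groups, k, k).  The dense path runs as
    k^2 shifted GEMMs on the contiguous padded frame; depthwise convolution
    (groups == in_ch == out_ch) uses shifted elementwise multiply-adds; other
    groupings loop over groups.
    """
    n, h, wd, c = x.data.shape
    out_ch, cg, k, _ = w.data.shape
    if c % groups or out_ch % groups or cg != c // groups:
        raise ValueError(
            f"incompatible conv grouping: in={c}, out={out_ch}, groups={groups}, "
            f"kernel expects {cg} input channels per group"
        )
    xp = (
        np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
        if padding
        else x.data
    )
    hp, wp = xp.shape[1], xp.shape[2]
    ho, wo = _conv_geometry(h, wd, k, stride, padding, dilation)
    depthwise = groups == c and out_ch == c

    y = np.zeros((n, ho, wo, out_ch), dtype=np.float32)
    if groups == 1:
        flat = xp.reshape(-1, c)
        for ki in range(k):
            for kj in range(k):
                wk = w.data[:, :, ki, kj].T  # (C, O)
                if stride == 1:
                    z = (flat @ wk).reshape(n, hp, wp, out_ch)
                    y += z[:, ki * dilation : ki * dilation + ho,
                           kj * dilation : kj * dilation + wo]
                else:
                    xs = np.ascontiguousarray(
                        xp[:, ki * dilation : ki * dilation + ho * stride : stride,
                           kj * dilation : kj * dilation + wo * stride : stride]
                    )
                    y += (xs.reshape(-1, c) @ wk).reshape(n, ho, wo, out_ch)
    elif depthwise:
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, ki * dilation : ki * dilation + ho * stride : stride,
                        kj * dilation : kj * dilation + wo * stride : stride]
                y += xs * w.data[:, 0, ki, kj]
    else:
        og = out_ch // groups
        for gi in range(groups):
            xg = np.ascontiguousarray(xp[..., gi * cg : (gi + 1) * cg])
            flat = xg.reshape(-1, cg)
            for ki in range(k):
                for kj in range(k):
                    wk = w.data[gi * og : (gi + 1) * og, :, ki, kj].T
                    if stride == 1:
                        z = (flat @ wk).reshape(n, hp, wp, og)
                        y[..., gi * og : (gi + 1) * og] += z[
                            :, ki * dilation : ki * dilation + ho,
                            kj * dilation : kj * dilation + wo]
                    else:
                        xs = np.ascontiguousarray(
                            xg[:, ki * dilation : ki * dilation + ho * stride : stride,
                               kj * dilation : kj * dilation + wo * stride : stride]
                        )
                        y[..., gi * og : (gi + 1) * og] += (
                            xs.reshape(-1, cg) @ wk
                        ).reshape(n, ho, wo, og)
    if b is not None:
        y += b.data

    def backward(g: np.ndarray) -> None:
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        need_dw = w.requires_grad
        need_dx = x.requires_grad
        if not (need_dw or need_dx):
            return
        dw = np.zeros_like(w.data) if need_dw else None
        dxp = np.zeros_like(xp) if need_dx else None
        gflat = g.reshape(-1, out_ch)
        for ki in range(k):
            for kj in range(k):
                hsl = slice(ki * dilation, ki * dilation + ho * stride, stride)
                wsl = slice(kj * dilation, kj * dilation + wo * stride, stride)
                if groups == 1:
                    if need_dw:
                        xs = xp[:, hsl, wsl]
                        # (C, O) = (C, positions) @ (positions, O)
                        dw[:, :, ki, kj] = np.tensordot(
                            g, xs, axes=([0, 1, 2], [0, 1, 2])
                        )
                    if need_dx:
                        t = (gflat @ w.data[:, :, ki, kj]).reshape(n, ho, wo, c)
                        dxp[:, hsl, wsl] += t
                elif depthwise:
                    xs = xp[:, hsl, wsl]
                    if need_dw:
                        dw[:, 0, ki, kj] = (g * xs).sum(axis=(0, 1, 2))
                    if need_dx:
                        dxp[:, hsl, wsl] += g * w.data[:, 0, ki, kj]
                else:
                    og = out_ch // groups
                    for gi in range(groups):
                        gg = g[..., gi * og : (gi + 1) * og]
                        xs = xp[:, hsl, wsl, gi * cg : (gi + 1) * cg]
                        if need_dw:
                            dw[gi * og : (gi + 1) * og, :, ki, kj] = np.tensordot(
                                gg, xs, axes=([0, 1, 2], [0, 1, 2])
                            )
                        if need_dx:
                            t = np.tensordot(
                                gg, w.data[gi * og : (gi + 1) * og, :, ki, kj],
                                axes=([3], [0]),
                            )
                            dxp[:, hsl, wsl, gi * cg : (gi + 1) * cg] += t
        if need_dw:
            w._accumulate(dw)
        if need_dx:
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor(y, parents=(x, w) + ((b,) if b is not None else ()), backward=backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W), channels-last."""
    if training:
        axes = (0, 1, 2)
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // x.data.shape[-1]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for stats
    else:
        mean, var = running_mean, running_var
    invstd = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * invstd
    y = gamma.data * xhat + beta.data

    def backward(g: np.ndarray) -> None:
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 1, 2)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxhat = g * gamma.data
            if training:
                m = x.data.size // x.data.shape[-1]
                sum_g = gxhat.sum(axis=(0, 1, 2))
                sum_gx = (gxhat * xhat).sum(axis=(0, 1, 2))
                dx = (gxhat - sum_g / m - xhat * (sum_gx / m)) * invstd
            else:
                dx = gxhat * invstd
            x._accumulate(dx)

    return Tensor(y, parents=(x, gamma, beta), backward=backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k; H and W must be divisible by k."""
    n, h, w, c = x.data.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial size {(h, w)} not divisible by {k}")
    v = x.data.reshape(n, h // k, k, w // k, k, c).transpose(0, 1, 3, 5, 2, 4)
    v = np.ascontiguousarray(v).reshape(n, h // k, w // k, c, k * k)
    idx = v.argmax(axis=-1)
    y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dv = np.zeros_like(v)
            np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
            dx = dv.reshape(n, h // k, w // k, c, k, k).transpose(0, 1, 4, 2, 5, 3)
            x._accumulate(np.ascontiguousarray(dx).reshape(n, h, w, c))

    return Tensor(y, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial dims, keeping (N, 1, 1, C)."""
    n, h, w, c = x.data.shape
    y = x.data.mean(axis=(1, 2), keepdims=True)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.data.shape))

    return Tensor(y, parents=(x,), backward=backward)


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    n, h, w, c = x.data.shape
    y = x.data.repeat(scale, axis=1).repeat(scale, axis=2)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dx = g.reshape(n, h, scale, w, scale, c).sum(axis=(2, 4))
            x._accumulate(dx)

    return Tensor(y, parents=(x,), backward=backward)
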