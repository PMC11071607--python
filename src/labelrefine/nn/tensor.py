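"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the dual-branch segmentation network needs:
2-D convolution (stride 1 or 2, zero padding), ReLU, elementwise addition,
nearest-neighbour 2x upsampling and a channel softmax. Activations use the
channel-last (N, H, W, C) layout, which keeps the convolution inner loops on
contiguous memory: a k x k convolution is computed as k^2 crop-and-matmul
taps rather than one big im2col gather. The graph is define-by-run;
``Tensor.backward`` seeds a gradient and accumulates into every reachable
parameter.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "add", "upsample2x", "smooth3",
           "concat_channels", "instance_norm", "softmax_channels", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (pure inference)."""

    def __enter__(self) -> None:
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc) -> None:
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Iterable["Tensor"] = (),
        backward: Callable[[np.ndarray], tuple] | None = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate ``grad`` (dL/dself) through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg


def _needs_graph(*tensors: Tensor) -> bool:
    if not _GRAD_ENABLED:
        return False
    return any(t.requires_grad or t._parents or t._backward for t in tensors)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution of an (N, H, W, Cin) input with a (k, k, Cin, Cout)
    kernel, zero padding; one matmul per kernel tap."""
    n, h, wid, cin = x.data.shape
    k, k2, cin_w, cout = w.data.shape
    assert k == k2 and cin == cin_w, "kernel/channel mismatch"
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    hp, wp = xp.shape[1:3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    rows = n * ho * wo
    kk = k * k

    def tap(arr: np.ndarray, idx: int) -> np.ndarray:
        i, j = divmod(idx, k)
        return arr[:, i : i + stride * (ho - 1) + 1 : stride,
                   j : j + stride * (wo - 1) + 1 : stride, :]

    # one contiguous block per kernel tap, then a batched matmul over taps:
    # fastest layout at the small channel counts this network uses
    cols = np.empty((kk, rows, cin), dtype=xp.dtype)
    for idx in range(kk):
        cols[idx] = tap(xp, idx).reshape(rows, cin)
    wk = w.data.reshape(kk, cin, cout)
    out = np.matmul(cols, wk).sum(axis=0)
    out += b.data
    out = out.reshape(n, ho, wo, cout)

    def backward(g: np.ndarray):
        gmat = np.ascontiguousarray(g).reshape(rows, cout)
        dw = np.matmul(cols.transpose(0, 2, 1), gmat[None]).reshape(w.data.shape)
        db = gmat.sum(axis=0)
        dcols = np.matmul(gmat[None], wk.transpose(0, 2, 1))  # (kk, rows, cin)
        dxp = np.zeros_like(xp)
        for idx in range(kk):
            tap(dxp, idx)[...] += dcols[idx].reshape(n, ho, wo, cin)
        dx = dxp[:, pad : pad + h, pad : pad + wid, :] if pad else dxp
        return ((x, dx), (w, dw), (b, db))

    if not _needs_graph(x, w, b):
        return Tensor(out)
    return Tensor(out, parents=(x, w, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray):
        return ((x, g * mask),)

    if not _needs_graph(x):
        return Tensor(out)
    return Tensor(out, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray):
        return ((a, g), (b, g))

    if not _needs_graph(a, b):
        return Tensor(out)
    return Tensor(out, parents=(a, b), backward=backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 in both spatial axes."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2)
    n, h, w, c = x.data.shape

    def backward(g: np.ndarray):
        dx = g.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
        return ((x, dx),)

    if not _needs_graph(x):
        return Tensor(out)
    return Tensor(out, parents=(x,), backward=backward)


def _smooth3_axis(a: np.ndarray, axis: int) -> np.ndarray:
    ap = np.concatenate([a.take([0], axis), a, a.take([-1], axis)], axis)
    lo = ap.take(range(0, a.shape[axis]), axis)
    mid = a
    hi = ap.take(range(2, a.shape[axis] + 2), axis)
    return 0.25 * lo + 0.5 * mid + 0.25 * hi


def _smooth3_adjoint_axis(g: np.ndarray, axis: int) -> np.ndarray:
    n = g.shape[axis]
    gp = np.zeros(g.shape[:axis] + (n + 2,) + g.shape[axis + 1 :], dtype=g.dtype)
    sl = [slice(None)] * g.ndim
    sl[axis] = slice(1, n + 1)
    gp[tuple(sl)] = g
    lo = gp.take(range(0, n), axis)
    hi = gp.take(range(2, n + 2), axis)
    out = 0.25 * lo + 0.5 * g + 0.25 * hi
    # edge-clamp contributions of the forward pass
    first = [slice(None)] * g.ndim
    first[axis] = slice(0, 1)
    last = [slice(None)] * g.ndim
    last[axis] = slice(n - 1, n)
    out[tuple(first)] += 0.25 * g[tuple(first)]
    out[tuple(last)] += 0.25 * g[tuple(last)]
    return out


def smooth3(x: Tensor) -> Tensor:
    """Separable [1/4, 1/2, 1/4] spatial smoothing with edge clamping.

    Composed after ``upsample2x`` this yields bilinear 2x upsampling,
    which avoids the half-pixel boundary bias of pure nearest-neighbour
    upsampling in the decoders."""
    out = _smooth3_axis(_smooth3_axis(x.data, 1), 2)

    def backward(g: np.ndarray):
        return ((x, _smooth3_adjoint_axis(_smooth3_adjoint_axis(g, 2), 1)),)

    if not _needs_graph(x):
        return Tensor(out)
    return Tensor(out, parents=(x,), backward=backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (N, H, W, C) tensors along the channel axis."""
    ca = a.data.shape[-1]
    out = np.concatenate([a.data, b.data], axis=-1)

    def backward(g: np.ndarray):
        return ((a, g[..., :ca]), (b, g[..., ca:]))

    if not _needs_graph(a, b):
        return Tensor(out)
    return Tensor(out, parents=(a, b), backward=backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance normalization: per sample and channel, zero-mean/unit-variance
    over the spatial axes, then a learnable affine transform. Batch-size
    independent and fully deterministic (no running statistics)."""
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    var = x.data.var(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def backward(g: np.ndarray):
        dgamma = (g * xhat).sum(axis=(0, 1, 2))
        dbeta = g.sum(axis=(0, 1, 2))
        gg = g * gamma.data
        m1 = gg.mean(axis=(1, 2), keepdims=True)
        m2 = (gg * xhat).mean(axis=(1, 2), keepdims=True)
        dx = inv * (gg - m1 - xhat * m2)
        return ((x, dx), (gamma, dgamma), (beta, dbeta))

    if not _needs_graph(x, gamma, beta):
        return Tensor(out)
    return Tensor(out, parents=(x, gamma, beta), backward=backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the trailing (channel) axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g: np.ndarray):
        dot = (g * p).sum(axis=-1, keepdims=True)
        return ((x, p * (g - dot)),)

    if not _needs_graph(x):
        return Tensor(p)
    return Tensor(p, parents=(x,), backward=backward)
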