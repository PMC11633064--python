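"""Minimal reverse-mode automatic differentiation over numpy arrays.

A define-by-run graph of :class:`Tensor` nodes, with exactly the operations
the three stage networks need: 3D convolution (stride 1, 'same' padding),
2× max pooling and nearest-neighbour upsampling, batch normalization, leaky
ReLU, sigmoid, channel concatenation, linear layers, global average pooling
and the two training losses. Everything is float32.

Gradients for convolution use the standard im2col identities: the weight
gradient is a matrix product of the unfolded input with the output gradient,
and the input gradient is a convolution of the output gradient with the
spatially flipped, channel-transposed kernels.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import numpy as np

EPS = 1e-7  # probability clamp for cross-entropy
LEAKY_SLOPE = 0.1


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar node through the whole graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------- elementwise

def leaky_relu(x: Tensor, slope: float = LEAKY_SLOPE) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def bw(g):
        x.accumulate(np.where(mask, g, slope * g))

    return _node(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x.accumulate(g * y * (1.0 - y))

    return _node(y, (x,), bw)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a.accumulate(g)
        b.accumulate(g)

    return _node(a.data + b.data, (a, b), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


# ------------------------------------------------------------------- linear

def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x:(N,F) @ w:(F,O) + b:(O,)"""
    out = x.data @ w.data + b.data

    def bw(g):
        x.accumulate(g @ w.data.T)
        w.accumulate(x.data.T @ g)
        b.accumulate(g.sum(axis=0))

    return _node(out, (x, w, b), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,D,H,W) -> (N,C) spatial mean."""
    n_spatial = np.prod(x.data.shape[2:])
    out = x.data.mean(axis=(2, 3, 4))

    def bw(g):
        x.accumulate(np.broadcast_to(
            (g / n_spatial)[:, :, None, None, None], x.data.shape))

    return _node(out, (x,), bw)


# -------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,D,H,W) zero-padded 'same' -> (C*k^3, N*D*H*W) for stride 1.

    Built offset-by-offset (k^3 slice copies per channel), which is far
    cheaper than reshaping an 8D sliding-window view.
    """
    pad = k // 2
    n, c, d, h, w = x.shape
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    else:
        xp = x
    cols = np.empty((c * k ** 3, n * d * h * w), dtype=np.float32)
    i = 0
    for ci in range(c):
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    cols[i] = xp[:, ci, dz:dz + d, dy:dy + h, dx:dx + w].ravel()
                    i += 1
    return cols


def _channels_first_flat(g: np.ndarray) -> np.ndarray:
    """(N,C,D,H,W) -> (C, N*D*H*W) contiguous."""
    n, c = g.shape[:2]
    return np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4).reshape(c, -1))


FFT_MIN_VOXELS = 32 ** 3  # below this, im2col + matmul is faster


def _conv_fft(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """FFT evaluation of the same 'same' correlation as the im2col path.

    For large spatial grids the im2col unfolding is memory-bound; circular
    convolution at length >= S+2 with a spatially flipped kernel reproduces
    the zero-padded linear result exactly. The input transform is cached for
    the weight-gradient computation.
    """
    from scipy import fft as sfft

    n, cin, d, h, wd = x.data.shape
    cout = w.data.shape[0]
    k = w.data.shape[2]
    shape = (d, h, wd)
    ls = tuple(sfft.next_fast_len(s + k - 1, real=True) for s in shape)
    xf = sfft.rfftn(x.data, s=ls, axes=(2, 3, 4))
    wrevf = sfft.rfftn(w.data[:, :, ::-1, ::-1, ::-1], s=ls, axes=(2, 3, 4))
    flat = xf.shape[2] * xf.shape[3] * xf.shape[4]
    of = np.einsum("ncf,ocf->nof", xf.reshape(n, cin, flat),
                   wrevf.reshape(cout, cin, flat))
    out = sfft.irfftn(of.reshape((n, cout) + xf.shape[2:]), s=ls, axes=(2, 3, 4))
    pad = k // 2
    out = out[:, :, pad:pad + d, pad:pad + h, pad:pad + wd].astype(np.float32)
    out = np.ascontiguousarray(out)
    out += b.data[None, :, None, None, None]

    def bw(g):
        gf = sfft.rfftn(g.astype(np.float32), s=ls, axes=(2, 3, 4))
        gflat = gf.reshape(n, cout, flat)
        # dW: correlation of input with output gradient at the k^3 offsets
        dwf = np.einsum("ncf,nof->ocf", xf.reshape(n, cin, flat), np.conj(gflat))
        dw_full = sfft.irfftn(dwf.reshape((cout, cin) + xf.shape[2:]),
                              s=ls, axes=(2, 3, 4))
        idx = [np.arange(-pad, k - pad) % l for l in ls]
        dw = dw_full[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]]
        w.accumulate(dw.astype(np.float32))
        b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            wf = sfft.rfftn(w.data, s=ls, axes=(2, 3, 4))
            dxf = np.einsum("nof,ocf->ncf", gflat, wf.reshape(cout, cin, flat))
            dx_full = sfft.irfftn(dxf.reshape((n, cin) + xf.shape[2:]),
                                  s=ls, axes=(2, 3, 4))
            dx = dx_full[:, :, pad:pad + d, pad:pad + h, pad:pad + wd]
            x.accumulate(dx.astype(np.float32))

    return _node(out, (x, w, b), bw)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same' 3D convolution, stride 1.

    x: (N,Cin,D,H,W); w: (Cout,Cin,k,k,k); b: (Cout,).
    """
    n, cin, d, h, wd = x.data.shape
    cout, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    if k > 1 and d * h * wd >= FFT_MIN_VOXELS:
        return _conv_fft(x, w, b)
    cols = _im2col(x.data, k)
    wm = w.data.reshape(cout, -1)
    out = (wm @ cols).reshape(cout, n, d, h, wd).transpose(1, 0, 2, 3, 4)
    out += b.data[None, :, None, None, None]

    def bw(g):
        gm = _channels_first_flat(g)
        w.accumulate((gm @ cols.T).reshape(w.data.shape))
        b.accumulate(gm.sum(axis=1))
        if x.requires_grad:
            # full correlation with flipped, channel-transposed kernels
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            gcols = _im2col(g, k)
            gx = (wf.reshape(cin, -1) @ gcols).reshape(
                cin, n, d, h, wd).transpose(1, 0, 2, 3, 4)
            x.accumulate(gx)

    return _node(np.ascontiguousarray(out), (x, w, b), bw)


# ------------------------------------------------------------------ pooling

def max_pool2(x: Tensor) -> Tensor:
    """2×2×2 max pooling, stride 2. Spatial dims must be even."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {(d, h, w)}")
    win = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        gx = gx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        x.accumulate(gx)

    return _node(np.ascontiguousarray(out), (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2× spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def bw(g):
        n, c, d, h, w = x.data.shape
        gx = g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
        x.accumulate(gx)

    return _node(out, (x,), bw)


# ----------------------------------------------------------------- batchnorm

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    In training mode batch statistics are used and the running estimates are
    updated in place; in evaluation mode the running estimates are used, so
    the forward pass is deterministic for fixed parameters.
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bw(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(shape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]
                s1 = gxhat.sum(axis=axes).reshape(shape)
                s2 = (gxhat * xhat).sum(axis=axes).reshape(shape)
                gx = (inv_std.reshape(shape) / m) * (m * gxhat - s1 - xhat * s2)
            else:
                gx = gxhat * inv_std.reshape(shape)
            x.accumulate(gx)

    return _node(out.astype(np.float32), (x, gamma, beta), bw)


# -------------------------------------------------------------------- losses

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against targets in [0,1].

    Computed in the numerically stable log-sum-exp form; the gradient is
    (sigmoid(logits) − targets) / n.
    """
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != logits.data.shape:
        raise ValueError(f"shape mismatch: {logits.data.shape} vs {t.shape}")
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = np.float32(loss.mean())

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-z))
        logits.accumulate(g * (p - t) / t.size)

    return _node(out, (logits,), bw)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber-style) loss: quadratic below beta, linear above."""
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out = np.float32(loss.mean())

    def bw(g):
        grad = np.where(ad < beta, d / beta, np.sign(d)) / d.size
        pred.accumulate(g * grad)

    return _node(out, (pred,), bw)


def scale(x: Tensor, c: float) -> Tensor:
    def bw(g):
        x.accumulate(g * c)

    return _node(x.data * c, (x,), bw)
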