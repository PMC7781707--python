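"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations that produced
it; :meth:`Tensor.backward` walks the graph in reverse topological order and
accumulates gradients.  Only the operations the embedding network needs are
implemented (convolution via im2col, pooling, batch normalisation, nearest
upsampling, elementwise arithmetic, fused losses).  Gradients are validated
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "is_param")

    def __init__(self, data, parents=(), is_param: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = None
        self.is_param = is_param

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> np.ndarray:
        return self.data

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"


def _wrap(data, parents, backward) -> Tensor:
    out = Tensor(data, parents=parents)
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    out = Tensor(out_data, parents=(a, b))

    def backward():
        a.accumulate(out.grad)
        b.accumulate(out.grad)

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward():
        a.accumulate(out.grad * b.data)
        b.accumulate(out.grad * a.data)

    out._backward = backward
    return out


def add_scalar(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data + s, parents=(a,))

    def backward():
        a.accumulate(out.grad)

    out._backward = backward
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, parents=(a,))

    def backward():
        a.accumulate(out.grad * s)

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def backward():
        a.accumulate(out.grad * mask)

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(a.data)
    out = Tensor(s, parents=(a,))

    def backward():
        a.accumulate(out.grad * s * (1.0 - s))

    out._backward = backward
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep).astype(a.data.dtype) / keep
    out = Tensor(a.data * mask, parents=(a,))

    def backward():
        a.accumulate(out.grad * mask)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x (n, d) @ w (d, k) + b (k,)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def backward():
        x.accumulate(out.grad @ w.data.T)
        w.accumulate(x.data.T @ out.grad)
        if b is not None:
            b.accumulate(out.grad.sum(axis=0))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution / pooling (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    n, c, H, W = xp.shape
    oh = (H - kh) // stride + 1
    ow = (W - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (s0, s1, s2, s3, s2 * stride, s3 * stride)
    cols = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    cols = np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, stride: int, oh: int, ow: int):
    n, c, H, W = xp_shape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += d6[
                :, :, i, j
            ]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation), x (n,c,H,W), w (oc,c,kh,kw)."""
    oc, c, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    w2 = w.data.reshape(oc, -1)
    out_data = np.matmul(w2, cols)  # (n, oc, oh*ow)
    if b is not None:
        out_data += b.data.reshape(1, oc, 1)
    out_data = out_data.reshape(-1, oc, oh, ow)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def backward():
        n = out.grad.shape[0]
        # one large GEMM beats n small ones: fold the batch into the columns
        g2 = np.ascontiguousarray(out.grad.reshape(n, oc, oh * ow).transpose(1, 0, 2)).reshape(oc, -1)
        cols2 = np.ascontiguousarray(cols.transpose(1, 0, 2)).reshape(cols.shape[1], -1)
        w.accumulate((g2 @ cols2.T).reshape(w.data.shape))
        if b is not None:
            b.accumulate(g2.sum(axis=1))
        dcols = (w2.T @ g2).reshape(cols.shape[1], n, oh * ow).transpose(1, 0, 2)
        dxp = _col2im(np.ascontiguousarray(dcols), xp.shape, kh, kw, stride, oh, ow)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x.accumulate(dxp)

    out._backward = backward
    return out


def maxpool2d(x: Tensor, k: int, stride: int, pad: int = 0) -> Tensor:
    n, c, H, W = x.data.shape
    if pad:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (pad, pad), (pad, pad)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    _, _, Hp, Wp = xp.shape
    oh = (Hp - k) // stride + 1
    ow = (Wp - k) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, oh, ow, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
    ).reshape(n, c, oh, ow, k * k)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def backward():
        dxp = np.zeros(xp.shape, dtype=out.grad.dtype)
        ni, ci, ohi, owi = np.indices((n, c, oh, ow), sparse=False)
        rows = ohi * stride + idx // k
        colx = owi * stride + idx % k
        np.add.at(dxp, (ni, ci, rows, colx), out.grad)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x.accumulate(dxp)

    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, H, W = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def backward():
        g = out.grad[:, :, None, None] / (H * W)
        x.accumulate(np.broadcast_to(g, x.data.shape).astype(out.grad.dtype))

    out._backward = backward
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 in both dimensions."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(out_data, parents=(x,))

    def backward():
        n, c, H2, W2 = out.grad.shape
        g = out.grad.reshape(n, c, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x.accumulate(g)

    out._backward = backward
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; running stats are updated in place."""
    if training:
        # contiguous (c, n*h*w) layout makes the reductions one fast pass each
        xr = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3).reshape(x.data.shape[1], -1))
        mean = xr.mean(axis=1)
        var = np.maximum((xr * xr).mean(axis=1) - mean * mean, 0.0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, gamma, beta))

    def backward():
        g = out.grad
        c = g.shape[1]
        gr = np.ascontiguousarray(g.transpose(1, 0, 2, 3).reshape(c, -1))
        xhr = np.ascontiguousarray(xhat.transpose(1, 0, 2, 3).reshape(c, -1))
        gx_sum = (gr * xhr).sum(axis=1)
        g_sum = gr.sum(axis=1)
        gamma.accumulate(gx_sum)
        beta.accumulate(g_sum)
        gs = gamma.data[None, :, None, None] / std[None, :, None, None]
        if training:
            nm = gr.shape[1]
            g_mean = (g_sum / nm)[None, :, None, None]
            gx_mean = (gx_sum / nm)[None, :, None, None]
            dx = gs * (g - g_mean - xhat * gx_mean)
        else:
            dx = gs * g
        x.accumulate(dx)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over the batch; labels are class indices."""
    z = logits.data
    n = z.shape[0]
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    lse = np.log(ez.sum(axis=1)) + zmax[:, 0]
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    out = Tensor(np.asarray(loss, dtype=z.dtype), parents=(logits,))

    def backward():
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        logits.accumulate(g * (out.grad / n))

    out._backward = backward
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def center_loss(embeddings: Tensor, centers: np.ndarray, labels: np.ndarray) -> Tensor:
    """Batch-averaged center loss: (1/2) * mean_i ||x_i - c_{y_i}||^2.

    The class centers are treated as constants here; they evolve through
    their own moving-average update rule, not through this gradient.
    """
    diff = embeddings.data - centers[labels]
    n = diff.shape[0]
    loss = 0.5 * float(np.sum(diff * diff)) / n
    out = Tensor(np.asarray(loss, dtype=embeddings.data.dtype), parents=(embeddings,))

    def backward():
        embeddings.accumulate(diff * (out.grad / n))

    out._backward = backward
    return out
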