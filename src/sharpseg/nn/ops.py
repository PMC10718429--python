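"""Differentiable operations for NHWC feature tensors.

Feature tensors are rank-4 ``(batch, height, width, channels)`` arrays.
Convolutions are stride-1 "same" (zero padding); downsampling is 2x2 max
pooling; upsampling is a 2x2 stride-2 transposed convolution. The fixed
3x3 sharpening convolution is depthwise with edge-replicate padding, so
constant feature maps are fixed points and no parameters are added.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import DTYPE, Var, as_var

# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def _np_sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _np_softplus(x):
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _elementwise(x: Var, fwd, dfd) -> Var:
    x = as_var(x)
    y = fwd(x.data)
    local = dfd(x.data, y)

    def backward(g):
        x.accumulate(g * local)

    return Var(y, parents=(x,), backward=backward)


def sigmoid(x: Var) -> Var:
    return _elementwise(x, _np_sigmoid, lambda _, y: y * (1.0 - y))


def relu(x: Var) -> Var:
    return _elementwise(x, lambda d: np.maximum(d, 0.0),
                        lambda d, _: (d > 0).astype(DTYPE))


def leaky_relu(x: Var, a: float = 0.1) -> Var:
    return _elementwise(x, lambda d: np.where(d > 0, d, a * d),
                        lambda d, _: np.where(d > 0, 1.0, a).astype(DTYPE))


def swish(x: Var) -> Var:
    def fwd(d):
        return d * _np_sigmoid(d)

    def dfd(d, _):
        s = _np_sigmoid(d)
        return s + d * s * (1.0 - s)

    return _elementwise(x, fwd, dfd)


def mish(x: Var) -> Var:
    def fwd(d):
        return d * np.tanh(_np_softplus(d))

    def dfd(d, _):
        t = np.tanh(_np_softplus(d))
        return t + d * (1.0 - t * t) * _np_sigmoid(d)

    return _elementwise(x, fwd, dfd)


ACTIVATION_OPS = {
    "relu": relu,
    "leaky_relu": leaky_relu,
    "swish": swish,
    "mish": mish,
    "sigmoid": sigmoid,
}


def add(a: Var, b: Var) -> Var:
    a, b = as_var(a), as_var(b)
    if a.shape != b.shape:
        raise ValueError(f"add shape mismatch: {a.shape} vs {b.shape}")

    def backward(g):
        a.accumulate(g)
        b.accumulate(g)

    return Var(a.data + b.data, parents=(a, b), backward=backward)


def mul_broadcast(x: Var, a: Var) -> Var:
    """Elementwise product where ``a`` broadcasts over the channel axis."""
    x, a = as_var(x), as_var(a)

    def backward(g):
        x.accumulate(g * a.data)
        ga = g * x.data
        if a.shape != g.shape:  # channel-broadcast: sum the expanded axis
            ga = ga.sum(axis=-1, keepdims=True)
        a.accumulate(ga)

    return Var(x.data * a.data, parents=(x, a), backward=backward)


def concat(parts, axis: int = -1) -> Var:
    parts = [as_var(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            p.accumulate(g[tuple(idx)])

    return Var(np.concatenate([p.data for p in parts], axis=axis),
               parents=tuple(parts), backward=backward)


# ---------------------------------------------------------------------------
# convolutions and pooling
# ---------------------------------------------------------------------------

def conv2d(x: Var, w: Var, b: Var = None) -> Var:
    """Stride-1 "same" convolution; ``w`` has shape (kh, kw, cin, cout)."""
    x, w = as_var(x), as_var(w)
    kh, kw, cin, cout = w.shape
    B, H, W, C = x.shape
    if C != cin:
        raise ValueError(f"channel mismatch: input {C}, kernel {cin}")
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        xm = x.data.reshape(-1, cin)
        wm = w.data.reshape(cin, cout)
        y = xm @ wm

        def backward(g):
            gm = g.reshape(-1, cout)
            w.accumulate((xm.T @ gm).reshape(w.shape))
            x.accumulate((gm @ wm.T).reshape(x.shape))
            if b is not None:
                b.accumulate(gm.sum(axis=0))

        out = Var(y.reshape(B, H, W, cout) + (b.data if b is not None else 0.0),
                  parents=tuple(p for p in (x, w, b) if p is not None),
                  backward=backward)
        return out

    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # patches: (B, H, W, cin, kh, kw) -> matrix rows ordered (kh, kw, cin)
    patches = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    pm = patches.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, kh * kw * cin)
    wm = w.data.reshape(kh * kw * cin, cout)
    y = (pm @ wm).reshape(B, H, W, cout)
    if b is not None:
        y = y + b.data

    def backward(g):
        gm = g.reshape(B * H * W, cout)
        w.accumulate((pm.T @ gm).reshape(w.shape))
        if b is not None:
            b.accumulate(gm.sum(axis=0))
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                wij = w.data[i, j]  # (cin, cout)
                gxp[:, i:i + H, j:j + W, :] += g @ wij.T
        x.accumulate(gxp[:, ph:ph + H, pw:pw + W, :])

    return Var(y, parents=tuple(p for p in (x, w, b) if p is not None),
               backward=backward)


def conv_transpose_2x2(x: Var, w: Var, b: Var = None) -> Var:
    """Stride-2 2x2 transposed convolution; ``w`` shape (2, 2, cin, cout)."""
    x, w = as_var(x), as_var(w)
    B, H, W, cin = x.shape
    if w.shape[:2] != (2, 2) or w.shape[2] != cin:
        raise ValueError("kernel must be (2, 2, cin, cout)")
    cout = w.shape[3]
    y = np.empty((B, 2 * H, 2 * W, cout), dtype=DTYPE)
    xm = x.data.reshape(-1, cin)
    for di in range(2):
        for dj in range(2):
            y[:, di::2, dj::2, :] = (xm @ w.data[di, dj]).reshape(B, H, W, cout)
    if b is not None:
        y += b.data

    def backward(g):
        gx = np.zeros_like(x.data)
        for di in range(2):
            for dj in range(2):
                gsub = g[:, di::2, dj::2, :]
                gm = gsub.reshape(-1, cout)
                wgrad = xm.T @ gm
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[di, dj] += wgrad
                gx += (gm @ w.data[di, dj].T).reshape(B, H, W, cin)
        x.accumulate(gx)
        if b is not None:
            b.accumulate(g.reshape(-1, cout).sum(axis=0))

    return Var(y, parents=tuple(p for p in (x, w, b) if p is not None),
               backward=backward)


def maxpool_2x2(x: Var) -> Var:
    x = as_var(x)
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("spatial dims must be even for 2x2 pooling")
    H2, W2 = H // 2, W // 2
    r = x.data.reshape(B, H2, 2, W2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    flat = r.reshape(B, H2, W2, C, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((B, H2, W2, C, 4), dtype=DTYPE)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(B, H2, W2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x.accumulate(gx.reshape(B, H, W, C))

    return Var(y, parents=(x,), backward=backward)


def dropout(x: Var, rate: float, rng: np.random.Generator,
            training: bool) -> Var:
    """Inverted dropout; identity when not training or rate == 0."""
    x = as_var(x)
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(DTYPE) / (1.0 - rate)

    def backward(g):
        x.accumulate(g * mask)

    return Var(x.data * mask, parents=(x,), backward=backward)


#: identity-plus-negative-Laplacian sharpening kernel; entries sum to 1
SHARPEN_KERNEL = np.array([[0.0, -1.0, 0.0],
                           [-1.0, 5.0, -1.0],
                           [0.0, -1.0, 0.0]], dtype=DTYPE)


def _edge_pad_adjoint(gxp: np.ndarray, H: int, W: int) -> np.ndarray:
    """Adjoint of 1-pixel edge-replicate padding on the spatial axes."""
    gx = gxp[:, 1:H + 1, 1:W + 1, :].copy()
    gx[:, 0, :, :] += gxp[:, 0, 1:W + 1, :]
    gx[:, -1, :, :] += gxp[:, H + 1, 1:W + 1, :]
    gx[:, :, 0, :] += gxp[:, 1:H + 1, 0, :]
    gx[:, :, -1, :] += gxp[:, 1:H + 1, W + 1, :]
    gx[:, 0, 0, :] += gxp[:, 0, 0, :]
    gx[:, 0, -1, :] += gxp[:, 0, W + 1, :]
    gx[:, -1, 0, :] += gxp[:, H + 1, 0, :]
    gx[:, -1, -1, :] += gxp[:, H + 1, W + 1, :]
    return gx


def sharpen(x: Var, kernel: np.ndarray = SHARPEN_KERNEL) -> Var:
    """Depthwise 3x3 convolution with a fixed kernel, edge-replicate padding.

    Adds no trainable parameters; gradients flow through to the input.
    """
    x = as_var(x)
    B, H, W, C = x.shape
    k = np.asarray(kernel, dtype=DTYPE)
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge")
    y = np.zeros_like(x.data)
    for i in range(3):
        for j in range(3):
            if k[i, j] != 0.0:
                y += k[i, j] * xp[:, i:i + H, j:j + W, :]

    def backward(g):
        gxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                if k[i, j] != 0.0:
                    gxp[:, i:i + H, j:j + W, :] += k[i, j] * g
        x.accumulate(_edge_pad_adjoint(gxp, H, W))

    return Var(y, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_dice_from_logits(logits: Var, target: np.ndarray,
                         epsilon: float = 1e-5):
    """Composite BCE + soft-Dice loss evaluated from logits.

    The cross-entropy is computed in the numerically stable logit form
    ``mean(softplus(z) - y*z)``; the Dice term uses the sigmoid
    probabilities. Returns ``(loss_var, bce_value, dice_loss_value)``.
    """
    logits = as_var(logits)
    y = np.asarray(target, dtype=DTYPE)
    if y.shape != logits.shape:
        raise ValueError(f"target shape {y.shape} != logits {logits.shape}")
    z = logits.data
    p = _np_sigmoid(z)
    n = y.size
    # -[y log p + (1-y) log(1-p)] simplifies to softplus(z) - y*z
    bce = float(np.mean(_np_softplus(z) - y * z))
    inter = float(np.sum(y * p))
    denom = float(np.sum(y)) + float(np.sum(p)) + epsilon
    dice = 2.0 * inter / denom
    dloss = 1.0 - dice
    total = bce + dloss

    def backward(g):
        # d(bce)/dz = (p - y)/n ; d(dice)/dp = (2y*denom - 2*inter)/denom^2
        gd_p = -(2.0 * y * denom - 2.0 * inter) / (denom * denom)
        gz = (p - y) / n + gd_p * p * (1.0 - p)
        logits.accumulate(g * gz)

    loss = Var(np.asarray(total), parents=(logits,), backward=backward)
    return loss, bce, dloss
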