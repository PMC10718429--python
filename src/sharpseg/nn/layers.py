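"""Parameterized layers and the Adam optimizer for the segmentation nets."""

from __future__ import annotations

import numpy as np

from . import ops
from .autodiff import DTYPE, Var


def glorot_uniform(shape, fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def he_uniform(shape, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """Kaiming fan-in init; suits the ReLU/swish activation family."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base: parameter bookkeeping shared by all layers."""

    def parameters(self) -> list:
        return [v for v in vars(self).values() if isinstance(v, Var) and v.trainable]


class Conv2D(Layer):
    def __init__(self, kh, kw, cin, cout, rng, activation=None, bias=True):
        fan_in = kh * kw * cin
        self.w = Var(he_uniform((kh, kw, cin, cout), fan_in, rng),
                     trainable=True)
        self.b = Var(np.zeros(cout, dtype=DTYPE), trainable=True) if bias else None
        self.activation = activation

    def __call__(self, x: Var) -> Var:
        y = ops.conv2d(x, self.w, self.b)
        if self.activation is not None:
            y = ops.ACTIVATION_OPS[self.activation](y)
        return y


class ConvTranspose2x2(Layer):
    """2x2 stride-2 learned upsampling."""

    def __init__(self, cin, cout, rng, bias=True):
        self.w = Var(glorot_uniform((2, 2, cin, cout), cin, 4 * cout, rng),
                     trainable=True)
        self.b = Var(np.zeros(cout, dtype=DTYPE), trainable=True) if bias else None

    def __call__(self, x: Var) -> Var:
        return ops.conv_transpose_2x2(x, self.w, self.b)


class ConvBlock(Layer):
    """Two same-padded 3x3 convolutions + activation, then dropout."""

    def __init__(self, cin, cout, rng, activation="swish", dropout_rate=0.0):
        self.conv1 = Conv2D(3, 3, cin, cout, rng, activation=activation)
        self.conv2 = Conv2D(3, 3, cout, cout, rng, activation=activation)
        self.dropout_rate = dropout_rate

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def __call__(self, x: Var, training: bool, rng: np.random.Generator) -> Var:
        h = self.conv2(self.conv1(x))
        return ops.dropout(h, self.dropout_rate, rng, training)


class AttentionGate(Layer):
    """Additive attention gate over a skip connection.

    The skip features ``x`` and the gating signal ``g`` (the coarser
    decoder-side feature map, brought to x's spatial size by a learned 2x2
    transposed convolution) each pass a 1x1 channel-wise convolution; their
    sum goes through swish, a 1x1 channel-collapse convolution and a sigmoid,
    giving per-pixel coefficients in (0, 1) that multiply ``x``. Bias terms
    are fixed to zero.
    """

    def __init__(self, c_skip, c_gate, rng, c_int=None):
        c_int = c_int or max(c_skip // 2, 1)
        self.upsample = ConvTranspose2x2(c_gate, c_skip, rng, bias=False)
        self.w_x = Conv2D(1, 1, c_skip, c_int, rng, bias=False)
        self.w_g = Conv2D(1, 1, c_skip, c_int, rng, bias=False)
        self.w_s = Conv2D(1, 1, c_int, 1, rng, bias=False)

    def parameters(self):
        return (self.upsample.parameters() + self.w_x.parameters()
                + self.w_g.parameters() + self.w_s.parameters())

    def coefficients(self, x: Var, g: Var) -> Var:
        gi = self.upsample(g)
        if gi.shape[1:3] != x.shape[1:3]:
            raise ValueError(f"gate signal {gi.shape} does not align with skip {x.shape}")
        h = ops.swish(ops.add(self.w_x(x), self.w_g(gi)))
        return ops.sigmoid(self.w_s(h))

    def __call__(self, x: Var, g: Var) -> Var:
        return ops.mul_broadcast(x, self.coefficients(x, g))


class Adam:
    """Adam with the configured (beta1, beta2, epsilon); decoupled from layers."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.9, eps=1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
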