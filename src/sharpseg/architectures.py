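"""The four segmentation architectures: UNet, Sharp UNet, Attention UNet,
and the fused Sharp Attention UNet.

All variants share one encoder-decoder backbone:

* encoder: ``depth`` levels, each two 3x3 "same" convolutions + activation
  followed by dropout (rate 0.1) and 2x2 max pooling; channel width doubles
  per level starting from ``base_filters``;
* bottleneck: one more double-convolution block;
* decoder: mirrored levels with 2x2 stride-2 transposed-convolution
  upsampling, skip concatenation, a double-convolution block with dropout
  0.5, and a final 1x1 convolution producing a single-channel logit map
  (sigmoid gives the probability map).

The variants differ only in what each skip connection carries:

=================  ========================================================
unet               raw encoder features
sharp              encoder features convolved with the fixed 3x3 sharpening
                   kernel — except the deepest skip, which stays raw (the
                   deepest sharpening filter is removed)
attention          encoder features weighted by an attention gate driven by
                   the one-level-coarser decoder signal
sharp_attention    BOTH the attention-gated features and the (sharpened or,
                   at the deepest skip, raw) encoder features, concatenated
=================  ========================================================

Sharpening adds no trainable parameters, so ``unet`` and ``sharp`` have
identical parameter counts at equal spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .nn import ops
from .nn.autodiff import DTYPE, Var
from .nn.layers import AttentionGate, Conv2D, ConvBlock, ConvTranspose2x2, Adam  # noqa: F401
from .nn.ops import SHARPEN_KERNEL, sharpen as _sharpen_op

VARIANTS = ("unet", "sharp", "attention", "sharp_attention")


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "sharp_attention"
    depth: int = 4
    base_filters: int = 16
    activation: str = "swish"
    dropout_encoder: float = 0.1
    dropout_decoder: float = 0.5
    input_side: int = 128

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.input_side % (2 ** self.depth):
            raise ValueError("input_side must be divisible by 2**depth")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls(**json.loads(text))


def sharpen_features(x, kernel: np.ndarray = SHARPEN_KERNEL):
    """Depthwise fixed-kernel sharpening of a feature tensor.

    Accepts a :class:`Var` or a plain ``(B, H, W, C)`` array; plain arrays
    come back as plain arrays.
    """
    if isinstance(x, Var):
        return _sharpen_op(x, kernel)
    return _sharpen_op(Var(x), kernel).data


def attention_gate(x, g, gate: AttentionGate):
    """Apply an attention gate: ``x * a(x, g)`` with coefficients in (0, 1)."""
    xv = x if isinstance(x, Var) else Var(x)
    gv = g if isinstance(g, Var) else Var(g)
    out = gate(xv, gv)
    return out if isinstance(x, Var) else out.data


class SegmentationModel:
    """One built architecture variant with its parameters."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        act = spec.activation
        d, base = spec.depth, spec.base_filters
        ch = [base * 2 ** l for l in range(d + 1)]  # ch[d] is the bottleneck

        self.encoder = []
        cin = 1
        for l in range(d):
            self.encoder.append(ConvBlock(cin, ch[l], rng, act, spec.dropout_encoder))
            cin = ch[l]
        self.bottleneck = ConvBlock(ch[d - 1], ch[d], rng, act, spec.dropout_encoder)

        uses_attention = spec.variant in ("attention", "sharp_attention")
        skip_multiplier = 2 if spec.variant == "sharp_attention" else 1
        self.upsamplers, self.gates, self.decoder = [], [], []
        for l in range(d - 1, -1, -1):
            self.upsamplers.append(ConvTranspose2x2(ch[l + 1], ch[l], rng))
            self.gates.append(AttentionGate(ch[l], ch[l + 1], rng)
                              if uses_attention else None)
            dec_in = ch[l] + skip_multiplier * ch[l]
            self.decoder.append(ConvBlock(dec_in, ch[l], rng, act, spec.dropout_decoder))
        self.head = Conv2D(1, 1, ch[0], 1, rng)
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    # -- introspection -----------------------------------------------------

    @property
    def n_attention_gates(self) -> int:
        return sum(g is not None for g in self.gates)

    @property
    def n_sharpen_sites(self) -> int:
        if self.spec.variant in ("sharp", "sharp_attention"):
            return self.spec.depth - 1  # the deepest sharpening filter is removed
        return 0

    def parameters(self) -> list:
        params = []
        for block in self.encoder:
            params += block.parameters()
        params += self.bottleneck.parameters()
        for up, gate, dec in zip(self.upsamplers, self.gates, self.decoder):
            params += up.parameters()
            if gate is not None:
                params += gate.parameters()
            params += dec.parameters()
        params += self.head.parameters()
        return params

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward -----------------------------------------------------------

    def forward(self, x, training: bool = False,
                rng: np.random.Generator = None) -> Var:
        """Run the network on a ``(B, H, W, 1)`` batch; returns the logit Var."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] % (2 ** self.spec.depth) or x.shape[2] % (2 ** self.spec.depth):
            raise ValueError("spatial dims must be divisible by 2**depth")
        rng = rng if rng is not None else self._dropout_rng
        d = self.spec.depth
        h = Var(x)
        skips = []
        for block in self.encoder:
            h = block(h, training, rng)
            skips.append(h)
            h = ops.maxpool_2x2(h)
        h = self.bottleneck(h, training, rng)

        variant = self.spec.variant
        for i, l in enumerate(range(d - 1, -1, -1)):
            gate_signal = h  # the one-level-coarser decoder-side feature map
            up = self.upsamplers[i](h)
            enc = skips[l]
            deepest = (i == 0)
            sharp_ok = not deepest  # the deepest sharpening filter is removed
            if variant == "unet":
                skip_parts = [enc]
            elif variant == "sharp":
                skip_parts = [_sharpen_op(enc) if sharp_ok else enc]
            elif variant == "attention":
                skip_parts = [self.gates[i](enc, gate_signal)]
            else:  # sharp_attention: gated features AND sharpened/raw features
                skip_parts = [self.gates[i](enc, gate_signal),
                              _sharpen_op(enc) if sharp_ok else enc]
            h = ops.concat([up] + skip_parts, axis=-1)
            h = self.decoder[i](h, training, rng)
        return self.head(h)

    def predict(self, x) -> np.ndarray:
        """Probability maps ``(B, H, W, 1)`` in (0, 1); dropout disabled."""
        logits = self.forward(x, training=False)
        return ops._np_sigmoid(logits.data)

    def predict_batched(self, x, batch_size: int = 16) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        outs = [self.predict(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    # -- weights -----------------------------------------------------------

    def get_weights(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = np.asarray(w, dtype=DTYPE).copy()

    def save(self, path) -> None:
        """Write weights as .npz with a JSON spec sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": w for i, w in enumerate(self.get_weights())})
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path, seed: int = 0) -> "SegmentationModel":
        path = Path(path)
        spec = ModelSpec.from_json(path.with_suffix(".json").read_text())
        model = cls(spec, seed=seed)
        with np.load(path.with_suffix(".npz")) as data:
            model.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> SegmentationModel:
    """Construct one architecture variant with seeded Glorot initialization."""
    return SegmentationModel(spec, seed=seed)
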