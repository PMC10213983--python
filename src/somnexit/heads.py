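"""Exit classifiers: modality recalibration (SE), transformer encoder, head.

Each exit k consumes the stacked feature maps of the first k modalities,
``F in R^{L x C x d}`` with ``L = k``.  A squeeze-and-excitation gate first
re-weights whole modalities: two shape-preserving 1x1 modality-mixing
convolutions give ``F'``, global average pooling squeezes ``F'`` to ``L``
scalars, two further 1x1 convolutions plus a sigmoid give the gate ``Mse``,
and the output is the residual ``F'' = F + Mse (x) F'``.  The stack is then
flattened to ``L*C`` tokens of length ``d``, passed through a transformer
encoder block (multi-head self-attention with residual layer norms and a
position-wise feed-forward network), flattened, and classified by two linear
layers into the five AASM stages.

The three exits are structurally identical up to ``L``; the printed encoder
wiring routes the second layer-norm residual back to the block *input*
(``O = LayerNorm(IO2 + X)``), and a config switch selects the conventional
``IO2``-only variant instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, as_tensor, concat, log_softmax, softmax
from .nn.layers import LayerNorm, _he_uniform

__all__ = [
    "EncoderConfig",
    "SEBlock",
    "MultiHeadSelfAttention",
    "EncoderBlock",
    "ExitHead",
    "stack_features",
]


@dataclass(frozen=True)
class EncoderConfig:
    n_heads: int = 8
    ff_dim: int = 16
    n_layers: int = 1
    head_hidden: int = 192
    n_classes: int = 5
    residual_as_printed: bool = True
    leaky_slope: float = 0.01

    def validate(self, d_model: int) -> None:
        if d_model % self.n_heads != 0:
            raise ValueError(
                f"token length {d_model} not divisible by {self.n_heads} heads"
            )


def stack_features(maps: list[Tensor]) -> Tensor:
    """Stack per-modality (B, C, d) maps into (B, L, C, d)."""
    shapes = {m.shape[1:] for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"modality feature shapes differ: {sorted(shapes)}")
    expanded = [m.reshape(m.shape[0], 1, m.shape[1], m.shape[2]) for m in maps]
    return expanded[0] if len(expanded) == 1 else concat(expanded, axis=1)


class SEBlock(Module):
    """Squeeze-and-excitation over the modality axis (L), residual output."""

    def __init__(self, n_modalities: int, rng: np.random.Generator):
        super().__init__()
        L = n_modalities
        self.L = L
        # shape-preserving modality-mixing convolutions (1x1 over C x d)
        self.register_parameter("w_pre0", _he_uniform(rng, L, (L, L)))
        self.register_parameter("b_pre0", np.zeros(L))
        self.register_parameter("w_pre1", _he_uniform(rng, L, (L, L)))
        self.register_parameter("b_pre1", np.zeros(L))
        # excitation convolutions on the pooled L-vector
        self.register_parameter("w_se0", _he_uniform(rng, L, (L, L)))
        self.register_parameter("b_se0", np.zeros(L))
        self.register_parameter("w_se1", _he_uniform(rng, L, (L, L)))
        self.register_parameter("b_se1", np.zeros(L))

    def _mix(self, f: Tensor, w: Tensor, b: Tensor) -> Tensor:
        # f: (B, L, C, d); mix along L: out[b,l] = sum_l' w[l,l'] f[b,l']
        B, L, C, d = f.shape
        flat = f.reshape(B, L, C * d)
        out = w @ flat + b.reshape(L, 1)
        return out.reshape(B, L, C, d)

    def forward(self, f: Tensor) -> Tensor:
        if f.shape[1] != self.L:
            raise ValueError(f"expected {self.L} stacked modalities, got {f.shape[1]}")
        fp = self._mix(f, self.w_pre0, self.b_pre0).leaky_relu(0.01)
        fp = self._mix(fp, self.w_pre1, self.b_pre1)  # F', same shape as F
        pooled = fp.mean(axis=(2, 3))  # (B, L)
        z = (pooled @ self.w_se0.swap_last() + self.b_se0).leaky_relu(0.01)
        mse = (z @ self.w_se1.swap_last() + self.b_se1).sigmoid()  # (B, L)
        gate = mse.reshape(mse.shape[0], self.L, 1, 1)
        return f + gate * fp  # F'' = F + Mse (x) F'


class MultiHeadSelfAttention(Module):
    """H-head scaled dot-product self-attention; heads concatenated.

    Projections map tokens of length ``d`` to ``d/H`` per head; scores are
    scaled by ``1/sqrt(d/H)``; there is no output projection (the head
    concatenation itself restores length ``d``).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.d_model, self.H = d_model, n_heads
        dh = d_model // n_heads
        self.register_parameter("wq", _he_uniform(rng, d_model, (n_heads, d_model, dh)))
        self.register_parameter("wk", _he_uniform(rng, d_model, (n_heads, d_model, dh)))
        self.register_parameter("wv", _he_uniform(rng, d_model, (n_heads, d_model, dh)))

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, n, d) -> (B, 1, n, d) broadcast against (H, d, dh)
        B, n, d = x.shape
        xh = x.reshape(B, 1, n, d)
        q = xh @ self.wq  # (B, H, n, dh)
        k = xh @ self.wk
        v = xh @ self.wv
        dh = d // self.H
        scores = (q @ k.swap_last()) * (1.0 / np.sqrt(dh))  # (B, H, n, n)
        attn = softmax(scores, axis=-1)
        heads = attn @ v  # (B, H, n, dh)
        return heads.transpose(0, 2, 1, 3).reshape(B, n, d)


class EncoderBlock(Module):
    """MHSA + residual layer-norm + position-wise feed-forward."""

    def __init__(self, d_model: int, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate(d_model)
        self.config = config
        self.mhsa = MultiHeadSelfAttention(d_model, config.n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.fc0 = Linear(d_model, config.ff_dim, rng)
        self.fc1 = Linear(config.ff_dim, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def forward(self, x: Tensor) -> Tensor:
        io1 = self.ln1(self.mhsa(x) + x)
        io2 = self.fc1(self.fc0(io1).leaky_relu(0.0)) + io1
        residual = x if self.config.residual_as_printed else io2
        return self.ln2(io2 + residual) if self.config.residual_as_printed \
            else self.ln2(io2)


class ExitHead(Module):
    """One exit: SE gate -> tokens -> encoder block(s) -> two linear layers."""

    def __init__(self, n_modalities: int, c: int, d: int,
                 config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        config.validate(d)
        self.L, self.c, self.d = n_modalities, c, d
        self.config = config
        self.se = SEBlock(n_modalities, rng)
        self.blocks = [EncoderBlock(d, config, rng) for _ in range(config.n_layers)]
        for i, b in enumerate(self.blocks):
            self._modules[f"block{i}"] = b
        self.fc_hidden = Linear(n_modalities * c * d, config.head_hidden, rng)
        self.fc_out = Linear(config.head_hidden, config.n_classes, rng)

    def logits(self, stacked: Tensor) -> Tensor:
        stacked = as_tensor(stacked)
        if stacked.shape[1:] != (self.L, self.c, self.d):
            raise ValueError(
                f"expected stacked features (B, {self.L}, {self.c}, {self.d}), "
                f"got {tuple(stacked.shape)}"
            )
        f = self.se(stacked)
        B = f.shape[0]
        x = f.reshape(B, self.L * self.c, self.d)  # LC tokens of length d
        for b in self.blocks:
            x = b(x)
        flat = x.reshape(B, self.L * self.c * self.d)
        h = self.fc_hidden(flat).leaky_relu(self.config.leaky_slope)
        return self.fc_out(h)

    def forward(self, stacked: Tensor) -> Tensor:
        """Class probabilities (rows sum to 1)."""
        return softmax(self.logits(stacked), axis=-1)

    def log_probs(self, stacked: Tensor) -> Tensor:
        return log_softmax(self.logits(stacked), axis=-1)
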