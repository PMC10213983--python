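"""Effective feature extraction: multi-scale 1-D convolutions with CBAM.

Each modality (EEG, EOG, EMG) gets its own extractor with two parallel
convolutional branches: a *small-kernel* branch (kernel 64 at 100 Hz -> each
window spans 0.64 s, resolving alpha/theta-range activity) and a
*large-kernel* branch (kernel 512 -> 5.12 s windows, resolving slow delta
waves).  Branch outputs are fused by channel concatenation and passed
through a 1-D convolutional block attention module (CBAM): channel attention
first (which feature maps matter), then spatial attention (which positions
within each map matter).  Every convolution is followed by batch
normalisation and a leaky-ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    LeakyReLU,
    MaxPool1d,
    Module,
    Sequential,
    Tensor,
    as_tensor,
    concat,
)

__all__ = [
    "EfemConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "EFEM",
    "build_branch",
    "branch_output_shape",
    "receptive_seconds",
    "channel_attention",
    "apply_channel_attention",
    "spatial_attention",
    "apply_spatial_attention",
]


def receptive_seconds(kernel: int, sampling_rate: float) -> float:
    """Temporal span of one convolution window, in seconds."""
    if kernel < 1 or sampling_rate <= 0:
        raise ValueError("kernel >= 1 and sampling_rate > 0 required")
    return kernel / sampling_rate


# A branch is a sequence of layer specs:
#   ("conv", filters, kernel, stride)  -- conv + batch-norm + leaky-ReLU
#   ("pool", kernel, stride)           -- max pooling
#   ("drop", p)                        -- dropout
DEFAULT_SMALL = (
    ("conv", 64, 64, 8),
    ("pool", 8, 8),
    ("drop", 0.5),
    ("conv", 32, 8, 1),
    ("conv", 56, 8, 1),
    ("pool", 4, 4),
)
DEFAULT_LARGE = (
    ("conv", 64, 512, 64),
    ("drop", 0.5),
    ("conv", 56, 6, 1),
    ("conv", 48, 6, 1),
    ("pool", 8, 3),
)


@dataclass(frozen=True)
class EfemConfig:
    """Hyperparameters of one modality's feature extractor.

    The figure-fixed elements of the default are the first small-branch conv
    (64 filters, kernel 64, stride 8) with 8/8 max pooling, and the 512-wide
    kernel of the large branch; the remaining widths are package defaults,
    overridable field-for-field from the run config.
    """

    small_branch: tuple = DEFAULT_SMALL
    large_branch: tuple = DEFAULT_LARGE
    cbam_reduction: int = 8
    cbam_spatial_kernel: int = 7
    leaky_slope: float = 0.01
    post: tuple = ()
    fusion: str = "concat"

    def __post_init__(self):
        for branch in (self.small_branch, self.large_branch):
            for spec in branch:
                if spec[0] == "conv" and (spec[2] < 1 or spec[3] < 1):
                    raise ValueError("kernel and stride must be >= 1")
        if self.fusion != "concat":
            raise ValueError("only channel-concatenation fusion is supported")
        if any(spec[0] == "conv" for spec in self.post):
            raise ValueError("post stack supports pool/drop layers only")
        c = self.output_channels()
        if c % self.cbam_reduction != 0:
            raise ValueError(
                f"cbam_reduction={self.cbam_reduction} must divide "
                f"fused channel count {c}"
            )

    @staticmethod
    def _branch_channels(branch) -> int:
        c = 1
        for spec in branch:
            if spec[0] == "conv":
                c = spec[1]
        return c

    def output_channels(self) -> int:
        """Fused channel count at the CBAM input."""
        return self._branch_channels(self.small_branch) + self._branch_channels(
            self.large_branch
        )

    def output_shape(self, input_length: int) -> tuple[int, int]:
        """(C, d) of the feature map for a given input length."""
        d_small = branch_output_shape(self.small_branch, input_length)[1]
        d_large = branch_output_shape(self.large_branch, input_length)[1]
        if d_small != d_large:
            raise ValueError(
                f"branch lengths differ after pooling ({d_small} vs {d_large}); "
                "adjust pooling specs"
            )
        c, d = self.output_channels(), d_small
        for spec in self.post:
            if spec[0] == "conv":
                c, d = spec[1], (d - spec[2]) // spec[3] + 1
            elif spec[0] == "pool":
                d = (d - spec[1]) // spec[2] + 1
        return c, d


def branch_output_shape(branch, input_length: int) -> tuple[int, int]:
    c, d = 1, input_length
    for spec in branch:
        if spec[0] == "conv":
            c, d = spec[1], (d - spec[2]) // spec[3] + 1
        elif spec[0] == "pool":
            d = (d - spec[1]) // spec[2] + 1
        elif spec[0] != "drop":
            raise ValueError(f"unknown layer spec {spec[0]!r}")
    return c, d


def build_branch(branch, slope: float, rng: np.random.Generator,
                 drop_rng: np.random.Generator) -> Sequential:
    mods: list[Module] = []
    c = 1
    for spec in branch:
        if spec[0] == "conv":
            _, filters, kernel, stride = spec
            mods += [
                Conv1d(c, filters, kernel, stride, rng=rng),
                BatchNorm1d(filters),
                LeakyReLU(slope),
            ]
            c = filters
        elif spec[0] == "pool":
            mods.append(MaxPool1d(spec[1], spec[2]))
        elif spec[0] == "drop":
            mods.append(Dropout(spec[1], drop_rng))
    return Sequential(*mods)


class ChannelAttention(Module):
    """Sigmoid gate per feature channel from pooled statistics.

    Global average- and max-pooling over positions each yield a C-vector;
    both pass through one shared bottleneck MLP (C -> C/r -> C); the two
    outputs are summed and squashed to (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError("reduction must divide channel count")
        hidden = channels // reduction
        self.channels = channels
        self.register_parameter("w0", _init(rng, channels, (channels, hidden)))
        self.register_parameter("b0", np.zeros(hidden))
        self.register_parameter("w1", _init(rng, hidden, (hidden, channels)))
        self.register_parameter("b1", np.zeros(channels))

    def _mlp(self, v: Tensor) -> Tensor:
        return (v @ self.w0 + self.b0).leaky_relu(0.0) @ self.w1 + self.b1

    def forward(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=-1)          # (B, C)
        mx = f.max(axis=-1)            # (B, C)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()  # (B, C)


class SpatialAttention(Module):
    """Sigmoid gate per position from channel-pooled maps.

    Channel-wise mean and max give two 1 x d maps; stacked and convolved with
    a single kernel-7 filter (same padding, so the output keeps length d).
    """

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(2, 1, kernel, stride=1, padding="same", rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=1, keepdims=True)   # (B, 1, d)
        mx = f.max(axis=1, keepdims=True)     # (B, 1, d)
        stacked = concat([avg, mx], axis=1)   # (B, 2, d)
        return self.conv(stacked).sigmoid()   # (B, 1, d)


class CBAM(Module):
    """Channel attention, then spatial attention, each applied by rescaling."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def forward(self, f: Tensor) -> Tensor:
        mc = self.channel(f)                       # (B, C)
        f1 = apply_channel_attention(f, mc)        # F'
        ms = self.spatial(f1)                      # (B, 1, d)
        return apply_spatial_attention(f1, ms)     # F''


def channel_attention(f, module: ChannelAttention) -> np.ndarray:
    """Functional wrapper returning the C-vector attention map as ndarray."""
    out = module(as_tensor(np.asarray(f)[None] if np.ndim(f) == 2 else f))
    return out.data[0] if np.ndim(f) == 2 else out.data


def apply_channel_attention(f: Tensor, mc: Tensor) -> Tensor:
    """Row-wise rescale: F' = Mc (x) F, preserving the C x d shape."""
    f, mc = as_tensor(f), as_tensor(mc)
    if mc.shape[-1] != f.shape[-2]:
        raise ValueError(
            f"channel map length {mc.shape[-1]} != channel count {f.shape[-2]}"
        )
    return f * mc.reshape(*mc.shape, 1)


def spatial_attention(f, module: SpatialAttention) -> np.ndarray:
    out = module(as_tensor(np.asarray(f)[None] if np.ndim(f) == 2 else f))
    return out.data[0] if np.ndim(f) == 2 else out.data


def apply_spatial_attention(f: Tensor, ms: Tensor) -> Tensor:
    """Column-wise rescale: F'' = Ms (x) F', preserving the C x d shape."""
    f, ms = as_tensor(f), as_tensor(ms)
    if ms.shape[-1] != f.shape[-1]:
        raise ValueError(
            f"spatial map length {ms.shape[-1]} != feature length {f.shape[-1]}"
        )
    return f * ms


class EFEM(Module):
    """One modality's extractor: two branches -> fusion -> CBAM -> post stack."""

    def __init__(self, config: EfemConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        drop_rng = drop_rng if drop_rng is not None else rng
        self.small = build_branch(config.small_branch, config.leaky_slope, rng, drop_rng)
        self.large = build_branch(config.large_branch, config.leaky_slope, rng, drop_rng)
        self.cbam = CBAM(
            config.output_channels(), config.cbam_reduction,
            config.cbam_spatial_kernel, rng,
        )
        self.post = build_branch(config.post, config.leaky_slope, rng, drop_rng) \
            if config.post else None

    def multi_scale(self, x: Tensor) -> Tensor:
        """Run both branches and fuse by channel concatenation."""
        try:
            s = self.small(x)
        except ValueError as e:
            raise ValueError(f"small branch: {e}") from None
        try:
            l = self.large(x)
        except ValueError as e:
            raise ValueError(f"large branch: {e}") from None
        if s.shape[-1] != l.shape[-1]:
            raise ValueError(
                f"branch lengths differ: small {s.shape[-1]} vs large {l.shape[-1]}"
            )
        return concat([s, l], axis=1)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, L_signal) or (B, 1, L_signal) -> feature map (B, C, d)."""
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        f = self.multi_scale(x)
        f = self.cbam(f)
        if self.post is not None:
            f = self.post(f)
        return f


def _init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)
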