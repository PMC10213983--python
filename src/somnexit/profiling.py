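"""Analytic cost profiling: parameter counts and per-path FLOPs.

Two counting routes are provided and cross-checked in the tests:

* the **analytic** route walks the model *configuration* and applies
  closed-form per-layer formulas (conv: ``2 k C_in C_out L_out`` plus bias;
  linear: ``2 n_in n_out`` plus bias; attention, normalisation and pooling
  terms itemised below), and
* the **instrumented** route runs the instantiated model on a probe batch,
  records the realised shapes of every layer, and applies the same formulas
  to those shapes; the parameter analogue simply sums ``p.size`` over the
  live parameter tensors.

The default convention counts 1 multiply-accumulate as 2 FLOPs; a ``macs``
toggle halves the multiply-add terms.

Two notions of "full path" cost exist for a multi-exit network and both are
reported: ``speed0`` — routing fixed to the final exit, where the early
classifier heads perform no computation (three EFEMs + final head only) —
and ``cumulative`` path costs, where the exit-k path includes every EFEM
*and head* up to k, which is what a gated sample actually traverses at a
positive Speed threshold.  Expected cost under an exit-fraction vector is
the convex combination of the cumulative path costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efem import EfemConfig
from .heads import EncoderConfig
from .model import ModelConfig

__all__ = [
    "FlopsReport",
    "count_params",
    "count_flops",
    "expected_flops",
    "instrumented_flops",
    "conv1d_flops",
    "conv1d_params",
]


# ---------------------------------------------------------------------------
# shared per-component formulas (used by both counting routes)
# ---------------------------------------------------------------------------

def conv1d_flops(kernel: int, c_in: int, c_out: int, l_out: int,
                 mac_factor: int = 2) -> int:
    return mac_factor * kernel * c_in * c_out * l_out + c_out * l_out


def conv1d_params(kernel: int, c_in: int, c_out: int, bias: bool = True) -> int:
    return kernel * c_in * c_out + (c_out if bias else 0)


def _linear_flops(n_in: int, n_out: int, rows: int, mf: int) -> int:
    return rows * (mf * n_in * n_out + n_out)


def _bn_flops(c: int, length: int) -> int:
    return 2 * c * length  # inference: scale + shift


def _lrelu_flops(n: int) -> int:
    return n


def _pool_flops(kernel: int, c: int, l_out: int) -> int:
    return (kernel - 1) * c * l_out  # comparisons


def _layernorm_flops(n: int, d: int) -> int:
    return 7 * n * d


def _channel_attention_flops(c: int, d: int, reduction: int, mf: int) -> int:
    h = c // reduction
    pools = 2 * c * d
    mlp = 2 * (mf * c * h + h + h + mf * h * c + c)
    combine = c + 4 * c          # sum + sigmoid
    apply = c * d                # row-wise rescale
    return pools + mlp + combine + apply


def _spatial_attention_flops(c: int, d: int, mf: int) -> int:
    pools = 2 * c * d
    sig = 4 * d
    apply = c * d
    return pools + sig + apply   # the kernel-7 conv is counted as a conv layer


def _se_flops(L: int, c: int, d: int, mf: int) -> int:
    mix = 2 * (mf * L * L * c * d + L * c * d + L * c * d)  # two 1x1 mixes + act
    pool = L * c * d
    gates = 2 * (mf * L * L + 2 * L) + 4 * L
    apply = 2 * L * c * d        # gate multiply + residual add
    return mix + pool + gates + apply


def _mhsa_flops(n: int, d: int, heads: int, mf: int) -> int:
    qkv = 3 * mf * n * d * d
    scores = mf * n * n * d + heads * n * n          # QK^T + scaling
    softmax = 5 * heads * n * n
    av = mf * n * n * d
    return qkv + scores + softmax + av


def _ff_flops(n: int, d: int, ff: int, mf: int) -> int:
    return _linear_flops(d, ff, n, mf) + n * ff + _linear_flops(ff, d, n, mf)


# ---------------------------------------------------------------------------
# analytic route (configuration arithmetic)
# ---------------------------------------------------------------------------

def _branch_flops(branch, input_length: int, mf: int) -> int:
    total, c, d = 0, 1, input_length
    for spec in branch:
        if spec[0] == "conv":
            _, filters, kernel, stride = spec
            l_out = (d - kernel) // stride + 1
            conv = conv1d_flops(kernel, c, filters, l_out)
            if mf == 1:
                conv = kernel * c * filters * l_out + filters * l_out
            total += conv + _bn_flops(filters, l_out) + _lrelu_flops(filters * l_out)
            c, d = filters, l_out
        elif spec[0] == "pool":
            l_out = (d - spec[1]) // spec[2] + 1
            total += _pool_flops(spec[1], c, l_out)
            d = l_out
    return total


def _efem_flops(cfg: EfemConfig, input_length: int, mf: int) -> int:
    total = _branch_flops(cfg.small_branch, input_length, mf)
    total += _branch_flops(cfg.large_branch, input_length, mf)
    c, d = cfg.output_shape(input_length)
    total += _channel_attention_flops(c, d, cfg.cbam_reduction, mf)
    # spatial-attention conv: same padding keeps length d
    total += conv1d_flops(cfg.cbam_spatial_kernel, 2, 1, d) if mf == 2 else (
        cfg.cbam_spatial_kernel * 2 * d + d
    )
    total += _spatial_attention_flops(c, d, mf)
    if cfg.post:
        total += _branch_flops(cfg.post, d, mf)
    return total


def _head_flops(L: int, c: int, d: int, enc: EncoderConfig, mf: int) -> int:
    n = L * c
    total = _se_flops(L, c, d, mf)
    per_block = (
        _mhsa_flops(n, d, enc.n_heads, mf)
        + 2 * _layernorm_flops(n, d)
        + _ff_flops(n, d, enc.ff_dim, mf)
    )
    total += enc.n_layers * per_block
    total += _linear_flops(n * d, enc.head_hidden, 1, mf) + enc.head_hidden
    total += _linear_flops(enc.head_hidden, enc.n_classes, 1, mf)
    return total


@dataclass
class FlopsReport:
    """Static and routing-weighted cost summary (counts are per the report's
    ``batch_size``; ``giga`` properties divide by 1e9)."""

    efem: dict[str, int]
    head: dict[int, int]
    cumulative: dict[int, int]      # gated exit-k path cost, per batch
    speed0: int                     # 3 EFEMs + final head only, per batch
    batch_size: int
    convention: str                 # "flops" (1 MAC = 2) or "macs"

    @property
    def speed0_giga(self) -> float:
        return self.speed0 / 1e9

    def cumulative_giga(self, k: int) -> float:
        return self.cumulative[k] / 1e9

    def expected(self, exit_fractions) -> float:
        return expected_flops(self, exit_fractions)


def count_flops(config: ModelConfig, batch_size: int = 1,
                convention: str = "flops") -> FlopsReport:
    """Analytic per-layer FLOPs of every stage and routing path."""
    if convention not in ("flops", "macs"):
        raise ValueError(f"unknown convention {convention!r}")
    mf = 2 if convention == "flops" else 1
    c, d = config.feature_shape()
    efem = {
        m: batch_size * _efem_flops(config.efem[m], config.input_length, mf)
        for m in config.modalities
    }
    head = {
        k: batch_size * _head_flops(
            k, c, d, config.encoder[config.modalities[k - 1]], mf
        )
        for k in (1, 2, 3)
    }
    mods = config.modalities
    cumulative = {}
    running = 0
    for k in (1, 2, 3):
        running += efem[mods[k - 1]] + head[k]
        cumulative[k] = running
    speed0 = sum(efem.values()) + head[3]
    report = FlopsReport(efem, head, cumulative, speed0, batch_size, convention)
    costs = [cumulative[k] for k in (1, 2, 3)]
    if not (costs[0] < costs[1] < costs[2]):
        raise AssertionError("cumulative path costs must strictly increase")
    return report


def expected_flops(report: FlopsReport, exit_fractions) -> float:
    """Routing-weighted expected cost (giga-FLOPs) over the gated paths."""
    f = np.asarray(exit_fractions, dtype=float)
    if f.shape != (3,) or abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("exit fractions must be 3 nonnegative values summing to 1")
    return float(sum(f[k - 1] * report.cumulative[k] for k in (1, 2, 3)) / 1e9)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def _branch_params(branch) -> int:
    total, c = 0, 1
    for spec in branch:
        if spec[0] == "conv":
            _, filters, kernel, _ = spec
            total += conv1d_params(kernel, c, filters) + 2 * filters  # + BN
            c = filters
    return total


def _efem_params(cfg: EfemConfig) -> int:
    total = _branch_params(cfg.small_branch) + _branch_params(cfg.large_branch)
    c = cfg.output_channels()
    h = c // cfg.cbam_reduction
    total += c * h + h + h * c + c                       # channel-attention MLP
    total += conv1d_params(cfg.cbam_spatial_kernel, 2, 1)  # spatial conv
    total += _branch_params(cfg.post) if cfg.post else 0
    return total


def _head_params(L: int, c: int, d: int, enc: EncoderConfig) -> int:
    total = 4 * (L * L + L)                              # SE mixes + gates
    per_block = 3 * d * d + 2 * (2 * d)                  # QKV + two layer norms
    per_block += d * enc.ff_dim + enc.ff_dim + enc.ff_dim * d + d
    total += enc.n_layers * per_block
    total += L * c * d * enc.head_hidden + enc.head_hidden
    total += enc.head_hidden * enc.n_classes + enc.n_classes
    return total


def count_params(config: ModelConfig, active_exits=(1, 2, 3)) -> int:
    """Exact parameter count of the sub-network reachable under the active
    exits (EFEMs up to the deepest active exit, plus the active heads)."""
    active = sorted(set(active_exits))
    if not active or any(k not in (1, 2, 3) for k in active):
        raise ValueError("active_exits must be a nonempty subset of {1,2,3}")
    c, d = config.feature_shape()
    total = 0
    for k in range(1, max(active) + 1):
        total += _efem_params(config.efem[config.modalities[k - 1]])
    for k in active:
        total += _head_params(k, c, d, config.encoder[config.modalities[k - 1]])
    return total


# ---------------------------------------------------------------------------
# instrumented route (realised shapes from a live forward pass)
# ---------------------------------------------------------------------------

def instrumented_flops(model, batch: dict, convention: str = "flops") -> int:
    """Trace one forward pass of the full path (speed-0 convention) and sum
    the same per-component formulas over the realised shapes."""
    from .efem import ChannelAttention, SpatialAttention
    from .heads import MultiHeadSelfAttention, SEBlock
    from .nn.layers import BatchNorm1d, Conv1d, LayerNorm, LeakyReLU, Linear, MaxPool1d

    mf = 2 if convention == "flops" else 1
    records: list[tuple[object, tuple]] = []
    # instrument only the sub-modules actually used at speed 0
    used = []
    for m in model.config.modalities:
        used += list(model._modules[f"efem_{m}"].modules())
    used += list(model.heads[2].modules())
    wrapped = []
    for m in used:
        if isinstance(m, (Conv1d, Linear, BatchNorm1d, LayerNorm, LeakyReLU,
                          MaxPool1d, MultiHeadSelfAttention, SEBlock,
                          ChannelAttention, SpatialAttention)):
            orig = m.forward

            def make(mod, fn):
                def traced(x):
                    records.append((mod, tuple(x.shape)))
                    return fn(x)
                return traced

            object.__setattr__(m, "forward", make(m, orig))
            wrapped.append((m, orig))
    try:
        model.eval()
        model.final_logits(batch)
    finally:
        for m, orig in wrapped:
            object.__setattr__(m, "forward", orig)

    total = 0
    batch_size = None
    for mod, shape in records:
        b = shape[0]
        batch_size = b
        if isinstance(mod, Conv1d):
            l_in = shape[-1] + (mod.kernel - 1 if mod.padding == "same" else 0)
            l_out = (l_in - mod.kernel) // mod.stride + 1
            total += b * (
                mf * mod.kernel * mod.c_in * mod.c_out * l_out + mod.c_out * l_out
            )
        elif isinstance(mod, Linear):
            rows = int(np.prod(shape[:-1]))  # includes the batch dimension
            total += _linear_flops(mod.n_in, mod.n_out, rows, mf)
        elif isinstance(mod, BatchNorm1d):
            total += b * _bn_flops(shape[1], shape[2])
        elif isinstance(mod, LayerNorm):
            total += _layernorm_flops(int(np.prod(shape[:-1])), shape[-1])
        elif isinstance(mod, LeakyReLU):
            total += int(np.prod(shape))
        elif isinstance(mod, MaxPool1d):
            l_out = (shape[-1] - mod.kernel) // mod.stride + 1
            total += b * _pool_flops(mod.kernel, shape[1], l_out)
        elif isinstance(mod, MultiHeadSelfAttention):
            total += b * _mhsa_flops(shape[1], shape[2], mod.H, mf)
        elif isinstance(mod, SEBlock):
            total += b * _se_flops(shape[1], shape[2], shape[3], mf)
        elif isinstance(mod, ChannelAttention):
            total += b * _channel_attention_flops(
                shape[1], shape[2], shape[1] // mod.w0.shape[1], mf
            )
        elif isinstance(mod, SpatialAttention):
            total += b * _spatial_attention_flops(shape[1], shape[2], mf)
    if batch_size is None:
        raise RuntimeError("no layers traced")
    return total
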