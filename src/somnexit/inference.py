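"""Entropy-gated early-exit inference controlled by the Speed threshold.

Each sample flows EEG extractor -> EEG exit; if its normalized predictive
entropy (``uncertainty``) is *strictly below* the Speed threshold it halts
and is classified as the argmax class; otherwise it continues to the EOG
exit and, failing that gate too, to the final exit, which has no gate.
Halted samples are removed from the batch between stages (progressive
sub-batching), so the deeper extractors genuinely never see them and the
cost accounting reflects real skipped computation.

Speed = 0 can never halt anything (uncertainty >= 0 is never < 0), so every
sample is classified by the final exit and — matching the published
behaviour — the two student heads perform no computation at all in that
case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .heads import stack_features
from .model import MODALITIES, MultiExitModel
from .profiling import FlopsReport, count_flops, expected_flops

__all__ = [
    "SpeedPolicy",
    "ExitTrace",
    "AdaptiveResult",
    "normalized_entropy",
    "decide_exit",
    "adaptive_predict",
    "speed_sweep",
]


@dataclass(frozen=True)
class SpeedPolicy:
    """Threshold on normalized entropy below which a sample halts early.

    One shared value by default; ``per_exit`` optionally overrides the
    threshold of each student exit separately.
    """

    speed: float = 0.0
    per_exit: tuple[float, float] | None = None

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.per_exit is not None and any(s < 0 for s in self.per_exit):
            raise ValueError("per-exit thresholds must be >= 0")

    def threshold(self, exit_index: int) -> float:
        if self.per_exit is not None:
            return self.per_exit[exit_index - 1]
        return self.speed


@dataclass
class ExitTrace:
    """Routing record of one sample."""

    uncertainties: list[float]
    exit_index: int
    predicted_class: int
    probs: np.ndarray


@dataclass
class AdaptiveResult:
    predictions: np.ndarray
    exit_index: np.ndarray
    traces: list[ExitTrace]
    exit_fractions: np.ndarray
    work: dict = field(default_factory=dict)


def normalized_entropy(p) -> float | np.ndarray:
    """Shannon entropy of ``p`` divided by its maximum log N; in [0, 1].

    Base-invariant (numerator and denominator share the log base); the
    0 log 0 convention handles one-hot inputs exactly.
    """
    p = np.asarray(p, dtype=float)
    if (p < -1e-9).any() or np.abs(p.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValueError("input is not a probability distribution")
    n = p.shape[-1]
    safe = np.where(p > 0, p, 1.0)
    num = (np.where(p > 0, p * np.log(safe), 0.0)).sum(axis=-1)
    out = num / np.log(1.0 / n)
    return float(out) if out.ndim == 0 else out


def decide_exit(uncertainty: float, policy: SpeedPolicy, exit_index: int = 1) -> bool:
    """True = halt here.  Strict comparison: halt iff u < Speed, so Speed=0
    never halts and a sample whose uncertainty equals the threshold
    continues."""
    return uncertainty < policy.threshold(exit_index)


def adaptive_predict(model: MultiExitModel, batch: dict,
                     policy: SpeedPolicy, chunk: int = 256) -> AdaptiveResult:
    """Route a batch through the gated exits under the given Speed policy."""
    from .nn import no_grad

    model.eval()
    n = len(np.asarray(batch[MODALITIES[0]]))
    gates_active = policy.per_exit is not None or policy.speed > 0
    if gates_active and getattr(model, "stage", 0) < 2:
        warnings.warn(
            "early exits are untrained (no stage-2 training recorded); "
            "routing with Speed > 0 is uncalibrated"
        )
    if n > chunk:  # bound peak memory: route chunk-wise and merge
        parts = []
        for lo in range(0, n, chunk):
            sub = {m: np.asarray(v)[lo:lo + chunk] for m, v in batch.items()}
            parts.append(adaptive_predict(model, sub, policy, chunk))
        preds = np.concatenate([p.predictions for p in parts])
        exit_idx = np.concatenate([p.exit_index for p in parts])
        traces = [t for p in parts for t in p.traces]
        fractions = np.array([(exit_idx == k).mean() for k in (1, 2, 3)])
        work = {"efem": {m: 0 for m in MODALITIES}, "head": {1: 0, 2: 0, 3: 0}}
        for p in parts:
            for m in MODALITIES:
                work["efem"][m] += p.work["efem"][m]
            for k in (1, 2, 3):
                work["head"][k] += p.work["head"][k]
        return AdaptiveResult(preds, exit_idx, traces, fractions, work)
    preds = np.full(n, -1, dtype=int)
    exit_idx = np.zeros(n, dtype=int)
    all_probs = [None] * n
    uncert: list[list[float]] = [[] for _ in range(n)]
    work = {"efem": {m: 0 for m in MODALITIES}, "head": {1: 0, 2: 0, 3: 0}}

    remaining = np.arange(n)
    feats_cache: list[np.ndarray] = []  # per-modality features of `remaining`
    with no_grad():
        for k in (1, 2, 3):
            mod = MODALITIES[k - 1]
            sub = {mod: np.asarray(batch[mod])[remaining]}
            feats_cache.append(model.modality_features(sub, mod).data)
            work["efem"][mod] += len(remaining)
            run_head = k == 3 or gates_active
            if not run_head:
                continue
            stacked = stack_features([_t(f) for f in feats_cache[:k]])
            probs = model.heads[k - 1](stacked).data
            work["head"][k] += len(remaining)
            if k < 3:
                u = np.atleast_1d(normalized_entropy(probs))
                halt = u < policy.threshold(k)
                for j, sample in enumerate(remaining):
                    uncert[sample].append(float(u[j]))
            else:
                halt = np.ones(len(remaining), dtype=bool)
            halted = remaining[halt]
            for j, sample in zip(np.flatnonzero(halt), halted):
                preds[sample] = int(probs[j].argmax())
                exit_idx[sample] = k
                all_probs[sample] = probs[j]
            keep = ~halt
            remaining = remaining[keep]
            feats_cache = [f[keep] for f in feats_cache]
            if len(remaining) == 0:
                break

    traces = [
        ExitTrace(uncert[i], int(exit_idx[i]), int(preds[i]), all_probs[i])
        for i in range(n)
    ]
    fractions = np.array([(exit_idx == k).mean() for k in (1, 2, 3)])
    return AdaptiveResult(preds, exit_idx, traces, fractions, work)


def _t(arr: np.ndarray):
    from .nn import Tensor

    return Tensor(arr)


def _all_exit_probs(model: MultiExitModel, batch: dict,
                    chunk: int = 256) -> list[np.ndarray]:
    """Ungated probabilities of all three exits, chunk-wise, no autodiff."""
    from .nn import no_grad

    model.eval()
    n = len(np.asarray(batch[MODALITIES[0]]))
    outs: list[list[np.ndarray]] = [[], [], []]
    with no_grad():
        for lo in range(0, n, chunk):
            sub = {m: np.asarray(v)[lo:lo + chunk] for m, v in batch.items()}
            feats = [model.modality_features(sub, m) for m in MODALITIES]
            for k in (1, 2, 3):
                outs[k - 1].append(
                    model.heads[k - 1](stack_features(feats[:k])).data
                )
    return [np.concatenate(o, axis=0) for o in outs]


def exit_uncertainties(model: MultiExitModel, batch: dict) -> np.ndarray:
    """(n, 2) normalized entropies of the two student exits for every sample
    (full ungated forward; used by the speed sweep)."""
    probs = _all_exit_probs(model, batch)
    return np.stack(
        [normalized_entropy(probs[0]), normalized_entropy(probs[1])], axis=1
    )


def speed_sweep(model: MultiExitModel, batch: dict, speeds,
                labels: np.ndarray | None = None,
                flops_report: FlopsReport | None = None) -> list[dict]:
    """Accuracy / exit-fraction / expected-cost curve over Speed values.

    The per-sample student uncertainties do not depend on Speed, so they are
    computed once and the routing at each Speed is derived by thresholding;
    the result is sample-for-sample identical to running
    :func:`adaptive_predict` at each Speed.
    """
    speeds = list(speeds)
    if not speeds:
        raise ValueError("speed list is empty")
    probs = _all_exit_probs(model, batch)
    u1 = normalized_entropy(probs[0])
    u2 = normalized_entropy(probs[1])
    if flops_report is None:
        flops_report = count_flops(model.config, batch_size=1)
    out = []
    for s in speeds:
        policy = SpeedPolicy(speed=float(s))
        halt1 = u1 < policy.threshold(1)
        halt2 = ~halt1 & (u2 < policy.threshold(2))
        exit_idx = np.where(halt1, 1, np.where(halt2, 2, 3))
        preds = np.where(
            halt1, probs[0].argmax(axis=1),
            np.where(halt2, probs[1].argmax(axis=1), probs[2].argmax(axis=1)),
        )
        fractions = np.array([(exit_idx == k).mean() for k in (1, 2, 3)])
        rec = {
            "speed": float(s),
            "exit_fractions": fractions,
            "expected_gflops": expected_flops(flops_report, fractions),
        }
        if labels is not None:
            rec["accuracy"] = float((preds == labels).mean())
        rec["predictions"] = preds
        out.append(rec)
    return out
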