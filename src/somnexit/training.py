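"""Two-stage training: backbone + final exit first, then distilled students.

Stage 1 trains the three feature extractors and the final (EMG) classifier
with cross-entropy on the five stage labels; the early exits are not
enabled.  Stage 2 freezes every stage-1 parameter and trains only the EEG
and EOG exits by self-distillation: the frozen final exit acts as the
teacher, and each student minimises the KL divergence from its predictive
distribution to the teacher's (optionally plus a weighted hard-label
cross-entropy term).  Stage 2 refuses to run without a stage-1 checkpoint.

All probabilities are clamped at 1e-12 before logarithms; KL magnitudes are
in nats (natural log, no distillation temperature).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .model import MODALITIES, MultiExitModel
from .nn import Adam, Tensor, log_softmax
from .signals import STAGES, EpochRecord

__all__ = [
    "TrainConfig",
    "kl_divergence",
    "self_distill_loss",
    "cross_entropy",
    "records_to_arrays",
    "train_single_exit",
    "train_multi_exit",
    "freeze_mask",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-12


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 256
    epochs_stage1: int = 30
    epochs_stage2: int = 10
    kd_weight: float = 1.0
    ce_weight_stage2: float = 0.0
    seed: int = 0
    normalize: bool = True
    patience: int | None = None
    stop_at_accuracy: float | None = None  # stage 1: stop once train acc reached

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.kd_weight < 0 or self.ce_weight_stage2 < 0:
            raise ValueError("loss weights must be nonnegative")

    @staticmethod
    def desk_scale(seed: int = 0) -> "TrainConfig":
        """Settings for CPU-scale studies on synthetic epochs (pairs with
        ``ModelConfig.reduced()``): smaller batches, moderate weight decay
        against memorisation of a small epoch set."""
        return TrainConfig(batch_size=64, epochs_stage1=18, epochs_stage2=8,
                           weight_decay=1e-3, seed=seed)


def _validate_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < -1e-9).any() or abs(p.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValueError("input is not a probability distribution")
    return np.clip(p, 0.0, None)


def kl_divergence(ps, pt) -> float | np.ndarray:
    """D_KL(ps || pt) = sum_i ps_i log(ps_i / pt_i), in nats.

    Teacher probabilities are clamped at 1e-12; zero student entries
    contribute 0 (the 0 log 0 convention).  Vector inputs give a scalar,
    batches give one value per row.
    """
    ps, pt = _validate_dist(ps), _validate_dist(pt)
    pt = np.clip(pt, _EPS, None)
    ps_safe = np.clip(ps, _EPS, None)
    terms = np.where(ps > 0, ps * (np.log(ps_safe) - np.log(pt)), 0.0)
    out = terms.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def self_distill_loss(ps1, ps2, pt) -> float:
    """Sum of the two students' KL divergences from the (fixed) teacher."""
    k1, k2 = kl_divergence(ps1, pt), kl_divergence(ps2, pt)
    return float(np.mean(k1) + np.mean(k2))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over a batch (differentiable)."""
    lp = log_softmax(logits, axis=-1)
    B = logits.shape[0]
    onehot = np.zeros(logits.shape)
    onehot[np.arange(B), labels] = 1.0
    return -(lp * Tensor(onehot)).sum() * (1.0 / B)


def _kl_loss_tensor(student_logits: Tensor, teacher_probs: np.ndarray) -> Tensor:
    """Differentiable mean KL(student || teacher); the teacher is a constant."""
    ls = log_softmax(student_logits, axis=-1)
    ps = ls.exp()
    log_pt = np.log(np.clip(teacher_probs, _EPS, None))
    B = student_logits.shape[0]
    return (ps * (ls - Tensor(log_pt))).sum() * (1.0 / B)


def records_to_arrays(records: list[EpochRecord], normalize: bool = True):
    """Stack epoch records into per-modality arrays plus integer labels."""
    batch: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        arr = np.stack([r.signals[m] for r in records])
        if normalize:
            mu = arr.mean(axis=1, keepdims=True)
            sd = arr.std(axis=1, keepdims=True)
            arr = (arr - mu) / np.where(sd > 0, sd, 1.0)
        batch[m] = arr
    labels = np.array([STAGES.index(r.label) for r in records])
    return batch, labels


def _subset(batch: dict, idx: np.ndarray) -> dict:
    return {m: v[idx] for m, v in batch.items()}


def freeze_mask(model: MultiExitModel, stage: int) -> dict[str, bool]:
    """Per-parameter trainability for the given stage (True = trainable)."""
    backbone = {name for name, _ in model.backbone_parameters()}
    mask = {}
    for name, _ in model.named_parameters():
        if stage == 1:
            mask[name] = name in backbone
        else:
            mask[name] = name not in backbone
    return mask


def train_single_exit(model: MultiExitModel, records: list[EpochRecord],
                      config: TrainConfig) -> dict:
    """Stage 1: cross-entropy on the final exit; students untouched."""
    batch, labels = records_to_arrays(records, config.normalize)
    params = [p for _, p in model.backbone_parameters()]
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = len(records)
    history = {"loss": [], "accuracy": []}
    model.train()
    for _ in range(config.epochs_stage1):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = _subset(batch, idx)
            logits = model.final_logits(sub)
            loss = cross_entropy(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite stage-1 loss {loss.data!r} at step {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
        if (config.stop_at_accuracy is not None
                and history["accuracy"][-1] >= config.stop_at_accuracy):
            break
    model.eval()
    model.stage = 1
    return history


def train_multi_exit(model: MultiExitModel, records: list[EpochRecord],
                     config: TrainConfig, stage1_state: dict | str) -> dict:
    """Stage 2: freeze the backbone, distill the two student exits."""
    if stage1_state is None:
        raise ValueError("stage-2 training requires a stage-1 checkpoint")
    if isinstance(stage1_state, str):
        state, meta = load_checkpoint(stage1_state)
        if meta.get("stage") != 1:
            raise ValueError(
                f"checkpoint stage {meta.get('stage')!r} is not a stage-1 checkpoint"
            )
        stage1_state = state
    model.load_state_dict(stage1_state)
    batch, labels = records_to_arrays(records, config.normalize)
    params = [p for _, p in model.student_parameters()]
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    n = len(records)
    history = {"loss": [], "acc_exit1": [], "acc_exit2": []}
    model.eval()  # frozen backbone: batch-norm uses running stats
    from .heads import stack_features

    for _ in range(config.epochs_stage2):
        order = rng.permutation(n)
        losses = []
        c1 = c2 = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = _subset(batch, idx)
            from .nn import no_grad

            with no_grad():  # frozen backbone + teacher need no graph
                feats = [
                    model.modality_features(sub, m).detach() for m in MODALITIES
                ]
                teacher = model.heads[2](stack_features(feats)).data
            logit1 = model.heads[0].logits(stack_features(feats[:1]))
            logit2 = model.heads[1].logits(stack_features(feats[:2]))
            loss = (_kl_loss_tensor(logit1, teacher)
                    + _kl_loss_tensor(logit2, teacher)) * config.kd_weight
            if config.ce_weight_stage2 > 0:
                loss = loss + config.ce_weight_stage2 * (
                    cross_entropy(logit1, labels[idx])
                    + cross_entropy(logit2, labels[idx])
                )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite stage-2 loss {loss.data!r} at step {start}"
                )
            if config.kd_weight > 0 or config.ce_weight_stage2 > 0:
                opt.zero_grad()
                loss.backward()
                opt.step()
            losses.append(float(loss.data))
            c1 += int((logit1.data.argmax(axis=1) == labels[idx]).sum())
            c2 += int((logit2.data.argmax(axis=1) == labels[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["acc_exit1"].append(c1 / n)
        history["acc_exit2"].append(c2 / n)
    model.stage = 2
    return history


def save_checkpoint(path: str, model: MultiExitModel, stage: int,
                    config: TrainConfig | None = None, seed: int | None = None):
    meta = {"stage": stage, "seed": seed,
            "model_config": model.config.to_dict(),
            "train_config": asdict(config) if config else None}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return state, meta


def load_model(path: str) -> tuple[MultiExitModel, dict]:
    """Rebuild a model from a checkpoint (config snapshot + weights)."""
    from .model import ModelConfig

    state, meta = load_checkpoint(path)
    model = MultiExitModel(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    model.stage = meta.get("stage", 0)
    model.eval()
    return model, meta
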