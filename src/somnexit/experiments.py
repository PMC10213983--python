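"""Desk-scale end-to-end study: the speed/accuracy trade-off on synthetic data.

Runs the complete regimen at CPU scale — synthesize a tiered epoch set,
train the backbone and final exit, freeze and distill the students, sweep
the Speed threshold on a held-out set — and summarises whether early exits
buy a substantial cost reduction at negligible accuracy loss.  Problem
sizes default to 1500 training / 500 evaluation epochs with the narrow
model configuration, which completes in a few minutes on one CPU.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .inference import speed_sweep
from .model import ModelConfig, MultiExitModel
from .profiling import count_flops
from .signals import SyntheticDatasetConfig, synthesize_dataset
from .training import (
    TrainConfig,
    records_to_arrays,
    train_multi_exit,
    train_single_exit,
)

__all__ = ["StudyResult", "scaled_down_study"]


@dataclass
class StudyResult:
    seed: int
    base_accuracy: float          # Speed = 0 (all samples at the final exit)
    base_gflops: float            # full gated three-exit path cost
    sweep: list[dict]
    best_point: dict | None      # best-saving sweep point meeting the bar
    backbone_frozen: bool         # stage-2 freeze contract held bitwise
    histories: dict = field(default_factory=dict)
    model: MultiExitModel | None = None

    @property
    def satisfied(self) -> bool:
        return self.best_point is not None and self.backbone_frozen


def _hash_state(state: dict, names) -> str:
    h = hashlib.sha256()
    for name in sorted(names):
        h.update(state[name].tobytes())
    return h.hexdigest()


def scaled_down_study(
    seed: int = 0,
    n_train: int = 1500,
    n_eval: int = 500,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    speeds=None,
    min_exit1_fraction: float = 0.3,
    max_accuracy_loss: float = 0.03,
    min_flops_drop: float = 0.15,
) -> StudyResult:
    """Train the two-stage model and evaluate the adaptive trade-off.

    ``best_point`` is the sweep record with the largest expected-cost saving
    among Speed values strictly inside (0, 1) that keep at least
    ``min_exit1_fraction`` of samples at the first exit while staying within
    ``max_accuracy_loss`` of the Speed-0 accuracy and saving at least
    ``min_flops_drop`` of the expected cost; ``None`` if no such Speed exists.
    """
    model_config = model_config or ModelConfig.reduced()
    train_config = train_config or TrainConfig.desk_scale(seed)
    speeds = np.linspace(0.0, 1.0, 21) if speeds is None else np.asarray(speeds)

    train_set = synthesize_dataset(
        SyntheticDatasetConfig(n_epochs=n_train, seed=seed * 2 + 1)
    )
    eval_set = synthesize_dataset(
        SyntheticDatasetConfig(n_epochs=n_eval, seed=seed * 2 + 2)
    )

    model = MultiExitModel(model_config, seed=seed)
    hist1 = train_single_exit(model, train_set, train_config)
    stage1_state = model.state_dict()
    backbone_names = [n for n, _ in model.backbone_parameters()]
    before = _hash_state(stage1_state, backbone_names)
    hist2 = train_multi_exit(model, train_set, train_config, stage1_state)
    after = _hash_state(model.state_dict(), backbone_names)

    batch, labels = records_to_arrays(eval_set, train_config.normalize)
    report = count_flops(model_config, batch_size=1)
    sweep = speed_sweep(model, batch, speeds, labels=labels, flops_report=report)

    base = next(r for r in sweep if r["speed"] == 0.0)
    base_acc, base_g = base["accuracy"], base["expected_gflops"]
    best = None
    for r in sweep:
        if not (0.0 < r["speed"] < 1.0):
            continue
        drop = 1.0 - r["expected_gflops"] / base_g
        meets = (
            r["exit_fractions"][0] >= min_exit1_fraction
            and r["accuracy"] >= base_acc - max_accuracy_loss
            and drop >= min_flops_drop
        )
        if meets and (best is None or drop > best["flops_drop"]):
            best = {**{k: r[k] for k in ("speed", "accuracy", "exit_fractions",
                                         "expected_gflops")},
                    "flops_drop": drop}
    return StudyResult(
        seed=seed,
        base_accuracy=base_acc,
        base_gflops=base_g,
        sweep=sweep,
        best_point=best,
        backbone_frozen=before == after,
        histories={"stage1": hist1, "stage2": hist2},
        model=model,
    )
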