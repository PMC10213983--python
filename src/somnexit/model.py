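"""The full multi-exit network: three EFEMs feeding three exit classifiers.

Exit 1 sees EEG features only (L=1), exit 2 sees EEG+EOG (L=2), exit 3 —
the final classifier and distillation teacher — sees all three modalities
(L=3).  Perturbing a deeper modality therefore cannot change an earlier
exit's output, which is what makes skipping deeper computation sound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .efem import EFEM, EfemConfig
from .heads import EncoderConfig, ExitHead, stack_features
from .nn import Module, Tensor, as_tensor

__all__ = ["ModelConfig", "MultiExitModel", "MODALITIES"]

MODALITIES = ("EEG", "EOG", "EMG")


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 3000
    efem: dict = field(default_factory=lambda: {m: EfemConfig() for m in MODALITIES})
    encoder: dict = field(
        default_factory=lambda: {m: EncoderConfig() for m in MODALITIES}
    )
    modalities: tuple = MODALITIES

    @staticmethod
    def reduced(width: int = 16, dropout: float = 0.3) -> "ModelConfig":
        """Narrow configuration for desk-scale (CPU) training experiments.

        Keeps the architecture — two branches with 64/512 kernels, CBAM,
        SE + encoder exits — but shrinks every free width.
        """
        small = (("conv", width, 64, 8), ("pool", 8, 8), ("drop", dropout),
                 ("conv", width, 8, 1), ("conv", width, 8, 1), ("pool", 4, 4))
        large = (("conv", width, 512, 64), ("drop", dropout),
                 ("conv", width, 6, 1), ("conv", width, 6, 1), ("pool", 8, 3))
        efem = EfemConfig(
            small_branch=small, large_branch=large,
            cbam_reduction=4 if (2 * width) % 4 == 0 else 1,
        )
        enc = EncoderConfig(n_heads=4, ff_dim=16, head_hidden=48)
        return ModelConfig(
            efem={m: efem for m in MODALITIES},
            encoder={m: enc for m in MODALITIES},
        )

    def to_dict(self) -> dict:
        import dataclasses

        return {
            "input_length": self.input_length,
            "modalities": list(self.modalities),
            "efem": {m: dataclasses.asdict(self.efem[m]) for m in self.modalities},
            "encoder": {
                m: dataclasses.asdict(self.encoder[m]) for m in self.modalities
            },
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        def tup(branch):
            return tuple(tuple(spec) for spec in branch)

        efem = {}
        for m, sub in d["efem"].items():
            sub = dict(sub)
            for key in ("small_branch", "large_branch", "post"):
                sub[key] = tup(sub[key])
            efem[m] = EfemConfig(**sub)
        encoder = {m: EncoderConfig(**sub) for m, sub in d["encoder"].items()}
        return ModelConfig(
            input_length=d["input_length"],
            efem=efem,
            encoder=encoder,
            modalities=tuple(d["modalities"]),
        )

    def feature_shape(self) -> tuple[int, int]:
        shapes = {
            self.efem[m].output_shape(self.input_length) for m in self.modalities
        }
        if len(shapes) != 1:
            raise ValueError(f"per-modality feature shapes differ: {sorted(shapes)}")
        return next(iter(shapes))


class MultiExitModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        c, d = config.feature_shape()
        self.c, self.d = c, d
        root = np.random.SeedSequence(seed)
        efem_seeds, head_seeds, drop_seed = root.spawn(3)
        drop_rng = np.random.default_rng(drop_seed)
        self.efems: dict[str, EFEM] = {}
        for m, ss in zip(config.modalities, efem_seeds.spawn(len(config.modalities))):
            e = EFEM(config.efem[m], np.random.default_rng(ss), drop_rng)
            self.efems[m] = e
            self._modules[f"efem_{m}"] = e
        self.heads: list[ExitHead] = []
        for k, ss in zip(range(1, 4), head_seeds.spawn(3)):
            h = ExitHead(
                k, c, d, config.encoder[config.modalities[k - 1]],
                np.random.default_rng(ss),
            )
            self.heads.append(h)
            self._modules[f"head{k}"] = h

    # -- forward pieces ---------------------------------------------------
    def modality_features(self, batch: dict, modality: str) -> Tensor:
        wav = as_tensor(np.asarray(batch[modality], dtype=np.float64))
        return self.efems[modality](wav)

    def exit_logits(self, batch: dict, k: int,
                    feats: list[Tensor] | None = None) -> Tensor:
        """Logits of exit k (1-based), computing only the first k EFEMs."""
        feats = feats if feats is not None else []
        while len(feats) < k:
            feats.append(
                self.modality_features(batch, self.config.modalities[len(feats)])
            )
        return self.heads[k - 1].logits(stack_features(feats[:k]))

    def exit_probs(self, batch: dict, k: int, chunk: int = 256) -> np.ndarray:
        """Exit-k probabilities, computed chunk-wise without autodiff graphs."""
        from .nn import no_grad, softmax

        n = len(np.asarray(batch[self.config.modalities[0]]))
        out = []
        with no_grad():
            for lo in range(0, n, chunk):
                sub = {m: np.asarray(v)[lo:lo + chunk] for m, v in batch.items()}
                out.append(softmax(self.exit_logits(sub, k), axis=-1).data)
        return np.concatenate(out, axis=0)

    def final_logits(self, batch: dict) -> Tensor:
        return self.exit_logits(batch, 3)

    # -- parameter grouping (needed by two-stage training) ---------------
    def backbone_parameters(self):
        """EFEM + final-exit parameters (stage-1 trainables)."""
        named = []
        for m in self.config.modalities:
            named += list(self._modules[f"efem_{m}"].named_parameters(f"efem_{m}."))
        named += list(self.heads[2].named_parameters("head3."))
        return named

    def student_parameters(self):
        """Early-exit parameters (stage-2 trainables)."""
        named = list(self.heads[0].named_parameters("head1."))
        named += list(self.heads[1].named_parameters("head2."))
        return named
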