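"""Distillation losses, the two-stage regimen, and the freeze contract."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnexit.model import MultiExitModel
from somnexit.signals import SyntheticDatasetConfig, synthesize_dataset
from somnexit.training import (
    TrainConfig,
    cross_entropy,
    freeze_mask,
    kl_divergence,
    load_checkpoint,
    load_model,
    save_checkpoint,
    self_distill_loss,
    train_multi_exit,
    train_single_exit,
)

from conftest import tiny_model_config


def random_dist(rng, n=5):
    p = rng.dirichlet(np.ones(n))
    return p


class TestKLDivergence:
    def test_zero_iff_equal(self, rng):
        p = random_dist(rng)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_onehot_vs_uniform_is_log5(self):
        one_hot = np.array([1.0, 0, 0, 0, 0])
        uniform = np.full(5, 0.2)
        assert kl_divergence(one_hot, uniform) == pytest.approx(np.log(5), abs=1e-12)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(1000):
            ps, pt = random_dist(rng), random_dist(rng)
            assert kl_divergence(ps, pt) >= 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gibbs_inequality_property(self, seed):
        r = np.random.default_rng(seed)
        ps, pt = random_dist(r), random_dist(r)
        assert kl_divergence(ps, pt) >= 0

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([0.5, 0.6, 0, 0, 0]), np.full(5, 0.2))


class TestSelfDistillLoss:
    def test_zero_when_students_match_teacher(self, rng):
        p = random_dist(rng)
        assert self_distill_loss(p, p, p) == pytest.approx(0.0, abs=1e-12)

    def test_additivity(self, rng):
        ps1, ps2, pt = (random_dist(rng) for _ in range(3))
        assert self_distill_loss(ps1, ps2, pt) == pytest.approx(
            kl_divergence(ps1, pt) + kl_divergence(ps2, pt)
        )

    def test_teacher_gradient_is_zero_by_construction(self, rng):
        """The trainable loss treats the teacher as a constant array, so no
        gradient can reach teacher parameters."""
        from somnexit.nn import Tensor
        from somnexit.training import _kl_loss_tensor

        logits = Tensor(rng.standard_normal((4, 5)), requires_grad=True)
        teacher_logits = Tensor(rng.standard_normal((4, 5)), requires_grad=True)
        teacher_probs = np.exp(teacher_logits.data)
        teacher_probs /= teacher_probs.sum(axis=1, keepdims=True)
        loss = _kl_loss_tensor(logits, teacher_probs)
        loss.backward()
        assert logits.grad is not None
        assert teacher_logits.grad is None


def _state_hash(model, names):
    h = hashlib.sha256()
    state = model.state_dict()
    for name in sorted(names):
        h.update(state[name].tobytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def trained():
    """One tiny two-stage run shared by the regimen tests."""
    records = synthesize_dataset(SyntheticDatasetConfig(n_epochs=40, seed=3))
    model = MultiExitModel(tiny_model_config(), seed=1)
    cfg = TrainConfig(batch_size=16, epochs_stage1=2, epochs_stage2=2, seed=0)
    student_names = [n for n, _ in model.student_parameters()]
    backbone_names = [n for n, _ in model.backbone_parameters()]
    student_before = _state_hash(model, student_names)
    hist1 = train_single_exit(model, records, cfg)
    student_after1 = _state_hash(model, student_names)
    stage1_state = model.state_dict()
    backbone_after1 = _state_hash(model, backbone_names)
    hist2 = train_multi_exit(model, records, cfg, stage1_state)
    return dict(
        model=model, records=records, cfg=cfg,
        student_names=student_names, backbone_names=backbone_names,
        student_before=student_before, student_after1=student_after1,
        backbone_after1=backbone_after1, hist1=hist1, hist2=hist2,
        stage1_state=stage1_state,
    )


class TestTwoStageRegimen:
    def test_stage1_leaves_students_bit_identical(self, trained):
        assert trained["student_before"] == trained["student_after1"]

    def test_stage2_leaves_backbone_bit_identical(self, trained):
        after2 = _state_hash(trained["model"], trained["backbone_names"])
        assert after2 == trained["backbone_after1"]

    def test_stage2_changes_students(self, trained):
        after2 = _state_hash(trained["model"], trained["student_names"])
        assert after2 != trained["student_after1"]

    def test_histories_record_every_epoch(self, trained):
        assert len(trained["hist1"]["loss"]) == 2
        assert len(trained["hist2"]["acc_exit1"]) == 2

    def test_stage2_requires_stage1_checkpoint(self, trained):
        model = MultiExitModel(tiny_model_config(), seed=2)
        with pytest.raises(ValueError, match="checkpoint"):
            train_multi_exit(model, trained["records"], trained["cfg"], None)

    def test_stage2_rejects_stage2_checkpoint_file(self, trained, tmp_path):
        path = str(tmp_path / "stage2.npz")
        save_checkpoint(path, trained["model"], stage=2)
        model = MultiExitModel(tiny_model_config(), seed=2)
        with pytest.raises(ValueError, match="not a stage-1"):
            train_multi_exit(model, trained["records"], trained["cfg"], path)

    def test_zero_loss_weights_leave_students_unchanged(self, trained):
        model = MultiExitModel(tiny_model_config(), seed=4)
        cfg = TrainConfig(batch_size=16, epochs_stage2=1, seed=0,
                          kd_weight=0.0, ce_weight_stage2=0.0)
        names = [n for n, _ in model.student_parameters()]
        train_multi_exit(model, trained["records"], cfg, trained["stage1_state"])
        before = {n: trained["stage1_state"][n] for n in names}
        after = model.state_dict()
        for n in names:
            assert np.array_equal(before[n], after[n])

    def test_freeze_mask_partitions_parameters(self, trained):
        model = trained["model"]
        mask2 = freeze_mask(model, stage=2)
        backbone = set(trained["backbone_names"])
        for name, trainable in mask2.items():
            assert trainable == (name not in backbone)

    def test_checkpoint_roundtrip_rebuilds_model(self, trained, tmp_path):
        path = str(tmp_path / "ck.npz")
        save_checkpoint(path, trained["model"], stage=2, config=trained["cfg"],
                        seed=0)
        rebuilt, meta = load_model(path)
        assert meta["stage"] == 2
        a = trained["model"].state_dict()
        b = rebuilt.state_dict()
        assert set(a) == set(b)
        for k in a:
            assert np.array_equal(a[k], b[k])


def test_seeded_training_is_reproducible():
    records = synthesize_dataset(SyntheticDatasetConfig(n_epochs=30, seed=8))
    cfg = TrainConfig(batch_size=16, epochs_stage1=2, seed=5)
    states = []
    for _ in range(2):
        model = MultiExitModel(tiny_model_config(), seed=9)
        train_single_exit(model, records, cfg)
        states.append(model.state_dict())
    for k in states[0]:
        assert np.array_equal(states[0][k], states[1][k])


def test_final_exit_learns_separable_synthetic_data():
    """300 EEG-separable epochs: stage-1 training accuracy reaches 0.9
    within 30 epochs."""
    records = synthesize_dataset(
        SyntheticDatasetConfig(n_epochs=300, tier_proportions=(1.0, 0.0, 0.0),
                               seed=2)
    )
    model = MultiExitModel(tiny_model_config(), seed=0)
    cfg = TrainConfig(batch_size=64, epochs_stage1=30, seed=0,
                      stop_at_accuracy=0.9)
    hist = train_single_exit(model, records, cfg)
    assert max(hist["accuracy"]) >= 0.9


def test_student_improves_during_stage2():
    """Distillation raises the EEG exit's accuracy above its stage-2
    initialisation on tiered synthetic data."""
    records = synthesize_dataset(SyntheticDatasetConfig(n_epochs=150, seed=21))
    model = MultiExitModel(tiny_model_config(), seed=3)
    cfg = TrainConfig(batch_size=32, epochs_stage1=6, epochs_stage2=6, seed=1)
    train_single_exit(model, records, cfg)
    hist2 = train_multi_exit(model, records, cfg, model.state_dict())
    assert hist2["acc_exit1"][-1] > hist2["acc_exit1"][0]


def test_non_finite_loss_aborts_with_diagnostics():
    records = synthesize_dataset(SyntheticDatasetConfig(n_epochs=10, seed=1))
    model = MultiExitModel(tiny_model_config(), seed=0)
    for p in model.heads[2].parameters():
        p.data[:] = np.inf
    cfg = TrainConfig(batch_size=8, epochs_stage1=1, seed=0)
    with pytest.raises(RuntimeError, match="non-finite"):
        train_single_exit(model, records, cfg)
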