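"""Exit classifiers: SE residual gate, attention oracle equivalence, encoder
wiring, probability contracts, and the modality-masking guarantee."""

import numpy as np
import pytest

from somnexit.heads import (
    EncoderBlock,
    EncoderConfig,
    ExitHead,
    MultiHeadSelfAttention,
    SEBlock,
    stack_features,
)
from somnexit.inference import normalized_entropy
from somnexit.nn import Tensor


class TestSEBlock:
    def test_zero_weights_make_residual_identity(self, rng):
        se = SEBlock(3, rng)
        for p in se.parameters():
            p.data[:] = 0
        f = rng.standard_normal((2, 3, 4, 5))
        out = se(Tensor(f)).data
        # F' = 0, Mse = sigma(0) = 0.5, so F'' = F + 0.5 * 0 = F
        assert np.allclose(out, f)

    def test_output_shape_is_input_shape(self, rng):
        se = SEBlock(2, rng)
        f = rng.standard_normal((3, 2, 5, 6))
        assert se(Tensor(f)).shape == f.shape

    def test_single_modality_scalar_gate(self):
        """L=1 degenerate stack, identity-like mixes: hand evaluation."""
        se = SEBlock(1, np.random.default_rng(0))
        se.w_pre0.data = np.eye(1)
        se.w_pre1.data = np.eye(1)
        se.w_se0.data = np.eye(1)
        se.w_se1.data = np.eye(1)
        for b in (se.b_pre0, se.b_pre1, se.b_se0, se.b_se1):
            b.data[:] = 0
        f = np.arange(6, dtype=float).reshape(1, 1, 2, 3)
        out = se(Tensor(f)).data
        pooled = f.mean()  # 2.5 -> gate sigma(2.5)
        gate = 1 / (1 + np.exp(-pooled))
        assert np.allclose(out, f + gate * f)

    def test_wrong_modality_count_rejected(self, rng):
        se = SEBlock(2, rng)
        with pytest.raises(ValueError, match="stacked modalities"):
            se(Tensor(np.zeros((1, 3, 4, 5))))


def mhsa_oracle(x, wq, wk, wv):
    """Double-loop scaled dot-product attention, one head at a time."""
    H = wq.shape[0]
    n, d = x.shape
    dh = d // H
    heads = []
    for h in range(H):
        q = x @ wq[h]
        k = x @ wk[h]
        v = x @ wv[h]
        out = np.zeros((n, dh))
        for i in range(n):
            scores = np.array([q[i] @ k[j] / np.sqrt(dh) for j in range(n)])
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            for j in range(n):
                out[i] += a[j] * v[j]
        heads.append(out)
    return np.concatenate(heads, axis=1)


class TestMHSA:
    def test_attention_rows_sum_to_one_via_uniform_value_trick(self, rng):
        """With V projecting to a constant, output = that constant exactly
        (softmax rows sum to 1)."""
        mhsa = MultiHeadSelfAttention(4, 2, rng)
        mhsa.wv.data[:] = 0
        x = Tensor(rng.standard_normal((1, 3, 4)))
        assert np.allclose(mhsa(x).data, 0.0)

    def test_identity_projections_identical_tokens(self):
        mhsa = MultiHeadSelfAttention(2, 1, np.random.default_rng(0))
        mhsa.wq.data = np.eye(2)[None]
        mhsa.wk.data = np.eye(2)[None]
        mhsa.wv.data = np.eye(2)[None]
        x = np.array([[[1.0, 2.0], [1.0, 2.0]]])
        out = mhsa(Tensor(x)).data
        assert np.allclose(out, x)  # uniform attention over identical values

    def test_two_token_integer_weight_oracle(self):
        mhsa = MultiHeadSelfAttention(2, 1, np.random.default_rng(0))
        wq = np.array([[[1.0, 0.0], [1.0, 1.0]]])
        wk = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        wv = np.array([[[2.0, 0.0], [0.0, 1.0]]])
        mhsa.wq.data, mhsa.wk.data, mhsa.wv.data = wq, wk, wv
        x = np.array([[1.0, 2.0], [3.0, -1.0]])
        got = mhsa(Tensor(x[None])).data[0]
        assert np.abs(got - mhsa_oracle(x, wq, wk, wv)).max() < 1e-6

    @pytest.mark.parametrize("n,d,H", [(2, 2, 1), (3, 4, 2), (4, 4, 4), (2, 3, 1)])
    def test_oracle_equivalence_on_toy_instances(self, n, d, H, rng):
        mhsa = MultiHeadSelfAttention(d, H, rng)
        x = rng.standard_normal((n, d))
        got = mhsa(Tensor(x[None])).data[0]
        expected = mhsa_oracle(x, mhsa.wq.data, mhsa.wk.data, mhsa.wv.data)
        assert np.abs(got - expected).max() < 1e-6

    def test_head_count_must_divide_token_length(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadSelfAttention(6, 4, rng)


class TestEncoderBlock:
    def test_output_shape_equals_input_shape(self, rng):
        blk = EncoderBlock(4, EncoderConfig(n_heads=2, ff_dim=6), rng)
        x = Tensor(rng.standard_normal((2, 5, 4)))
        assert blk(x).shape == x.shape

    def test_zero_weight_wiring_matches_hand_trace(self, rng):
        """Zero MHSA and FF weights reduce the block to layer norms around
        the printed residual structure; traced on a 2 x 4 grid."""
        cfg = EncoderConfig(n_heads=2, ff_dim=3, residual_as_printed=True)
        blk = EncoderBlock(4, cfg, rng)
        for p in blk.mhsa.parameters():
            p.data[:] = 0
        for p in list(blk.fc0.parameters()) + list(blk.fc1.parameters()):
            p.data[:] = 0
        x = rng.standard_normal((2, 4))

        def ln(v):
            mu = v.mean(axis=-1, keepdims=True)
            var = v.var(axis=-1, keepdims=True)
            return (v - mu) / np.sqrt(var + 1e-5)

        io1 = ln(0 + x)       # MHSA = 0
        io2 = 0 + io1         # FF = 0
        expected = ln(io2 + x)  # printed residual back to the block input
        got = blk(Tensor(x[None])).data[0]
        assert np.abs(got - expected).max() < 1e-6

    def test_conventional_residual_variant_differs(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 4)))
        a = EncoderBlock(4, EncoderConfig(n_heads=2, residual_as_printed=True),
                         np.random.default_rng(3))(x).data
        b = EncoderBlock(4, EncoderConfig(n_heads=2, residual_as_printed=False),
                         np.random.default_rng(3))(x).data
        assert not np.allclose(a, b)


class TestExitHead:
    def test_probabilities_sum_to_one(self, rng):
        head = ExitHead(2, 3, 4, EncoderConfig(n_heads=2, ff_dim=4,
                                               head_hidden=8), rng)
        f = Tensor(rng.standard_normal((5, 2, 3, 4)))
        p = head(f).data
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert p.shape == (5, 5)

    def test_softmax_shift_invariance(self, rng):
        head = ExitHead(1, 3, 4, EncoderConfig(n_heads=2, ff_dim=4,
                                               head_hidden=8), rng)
        f = Tensor(rng.standard_normal((2, 1, 3, 4)))
        logits = head.logits(f)
        from somnexit.nn import softmax

        p1 = softmax(logits, -1).data
        p2 = softmax(logits + 3.7, -1).data
        assert np.allclose(p1, p2, atol=1e-12)

    def test_untrained_head_near_uniform_probs_high_uncertainty(self, rng):
        """He-initialised head on standardized random features: predictive
        entropy close to its maximum."""
        head = ExitHead(1, 8, 8, EncoderConfig(n_heads=4, ff_dim=8,
                                               head_hidden=16), rng)
        f = Tensor(rng.standard_normal((20, 1, 8, 8)) * 0.1)
        p = head(f).data
        u = normalized_entropy(p)
        # far from one-hot: high entropy on average, never confident
        assert u.mean() > 0.7 and u.min() > 0.5

    def test_stacking_requires_matching_shapes(self, rng):
        a = Tensor(rng.standard_normal((1, 3, 4)))
        b = Tensor(rng.standard_normal((1, 3, 5)))
        with pytest.raises(ValueError, match="differ"):
            stack_features([a, b])


class TestModalityContract:
    """Exit k must consume exactly the first k modalities: perturbing EMG
    cannot change the EEG or EOG exits, and perturbing EOG cannot change the
    EEG exit."""

    def test_earlier_exits_blind_to_deeper_modalities(self, tiny_model, rng):
        batch = {m: rng.standard_normal((3, 3000)) for m in ("EEG", "EOG", "EMG")}
        p1 = tiny_model.exit_probs(batch, 1)
        p2 = tiny_model.exit_probs(batch, 2)
        perturbed = dict(batch)
        perturbed["EMG"] = rng.standard_normal((3, 3000)) * 10
        assert np.array_equal(tiny_model.exit_probs(perturbed, 1), p1)
        assert np.array_equal(tiny_model.exit_probs(perturbed, 2), p2)
        perturbed["EOG"] = rng.standard_normal((3, 3000)) * 10
        assert np.array_equal(tiny_model.exit_probs(perturbed, 1), p1)
        assert not np.array_equal(tiny_model.exit_probs(perturbed, 2), p2)

    def test_three_heads_structurally_identical_up_to_L(self, tiny_model):
        for k, head in enumerate(tiny_model.heads, start=1):
            assert head.L == k
            assert head.config == tiny_model.heads[0].config
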